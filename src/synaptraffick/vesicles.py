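"""Surface/total receptor ratio, vesicle counting and lysosomal colocalization.

Two live-imaging assays are covered.  In the NH4Cl reveal assay an image
of surface-only pH-sensitive receptor signal is followed by one after
NH4Cl perfusion collapses organellar pH gradients and unquenches
intracellular receptors: the surface/total ratio and the count of *new*
large vesicular objects (visible only post-NH4Cl) quantify the
intracellular pool.  In the lysosomal targeting assay, far-red dye-pulse-
labeled surface receptors are scored for colocalization with a
Lysotracker-defined lysosome mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import gaussian
from skimage.measure import label as _cc_label
from skimage.measure import regionprops

from .puncta import ChannelImage, threshold_mask

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Spot:
    id: int
    x_um: float
    y_um: float
    diameter_um: float
    peak: float


@dataclass
class SpotSet:
    spots: list[Spot]
    source_image: str = ""

    def __len__(self) -> int:
        return len(self.spots)


@dataclass(frozen=True)
class RatioResult:
    ratio: float | None
    surface_sum: float
    total_sum: float
    flagged: bool = False


def surface_total_ratio(
    surface_img: ChannelImage,
    total_img: ChannelImage,
    background_surface: float = 0.0,
    background_total: float = 0.0,
    roi_mask: np.ndarray | None = None,
    smoothing_sigma_um: float = 0.0,
) -> RatioResult:
    """Surface/total receptor ratio over an ROI, background-subtracted.

    ratio = (surface sum - background) / (total sum - background), with
    the per-pixel background levels scaled by the ROI pixel count.  A
    non-positive denominator flags the ROI instead of dividing.
    The ratio is invariant to a common positive gain on both images.
    """
    if surface_img.shape != total_img.shape:
        raise ValueError("surface and total images must share one shape")
    s_px, t_px = surface_img.pixels, total_img.pixels
    if smoothing_sigma_um > 0:
        sig = smoothing_sigma_um / surface_img.pixel_size_um
        s_px = gaussian(s_px, sigma=sig, preserve_range=True)
        t_px = gaussian(t_px, sigma=sig, preserve_range=True)
    if roi_mask is None:
        roi_mask = np.ones(surface_img.shape, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    n = int(roi_mask.sum())
    s = float(s_px[roi_mask].sum()) - background_surface * n
    t = float(t_px[roi_mask].sum()) - background_total * n
    if t <= 0:
        return RatioResult(ratio=None, surface_sum=s, total_sum=t, flagged=True)
    return RatioResult(ratio=s / t, surface_sum=s, total_sum=t)


def detect_spots(
    img: ChannelImage,
    nominal_size_um: float = 0.75,
    intensity_floor: float = 100.0,
    circularity_min: float = 0.8,
    diameter_window: tuple[float, float] = (0.4, 2.0),
) -> SpotSet:
    """Scale-matched detection of bright circular vesicle objects.

    The image is smoothed at a quarter of the nominal object size, the
    stringent ``intensity_floor`` is applied, and connected regions are
    kept when their equivalent diameter falls within
    ``diameter_window * nominal_size_um`` and their circularity
    (minor/major axis ratio) is >= ``circularity_min``.  The nominal size
    is treated as the object diameter.
    """
    if not nominal_size_um > 2 * img.pixel_size_um:
        raise ValueError("nominal spot size must exceed 2 pixels")
    log.info("detect_spots: nominal size %.2f um interpreted as object diameter",
             nominal_size_um)
    sigma_px = nominal_size_um / 4.0 / img.pixel_size_um
    sm = gaussian(img.pixels, sigma=sigma_px, preserve_range=True)
    mask = sm >= intensity_floor
    lab = _cc_label(mask, connectivity=2)
    lo = diameter_window[0] * nominal_size_um
    hi = diameter_window[1] * nominal_size_um
    spots: list[Spot] = []
    next_id = 1
    for rp in regionprops(lab, intensity_image=img.pixels):
        d_um = rp.equivalent_diameter_area * img.pixel_size_um
        if not (lo <= d_um <= hi):
            continue
        if rp.axis_major_length > 0:
            circ = rp.axis_minor_length / rp.axis_major_length
        else:
            circ = 1.0  # single pixel / degenerate region: trivially round
        if circ < circularity_min:
            continue
        r, c = rp.centroid
        spots.append(Spot(id=next_id,
                          x_um=(c + 0.5) * img.pixel_size_um,
                          y_um=(r + 0.5) * img.pixel_size_um,
                          diameter_um=float(d_um),
                          peak=float(rp.intensity_max)))
        next_id += 1
    return SpotSet(spots=spots, source_image=img.channel)


def match_spots(pre: SpotSet, post: SpotSet,
                match_radius_um: float = 0.5) -> list[tuple[int, int]]:
    """Greedy nearest-neighbour matching of post spots to pre spots.

    Candidate pairs within the radius are taken in ascending distance,
    ties broken lexicographically on (pre id, post id); each spot matches
    at most once.
    """
    pairs = []
    for p in pre.spots:
        for q in post.spots:
            d = np.hypot(p.x_um - q.x_um, p.y_um - q.y_um)
            if d <= match_radius_um:
                pairs.append((d, p.id, q.id))
    pairs.sort()
    used_pre, used_post, out = set(), set(), []
    for _, pid, qid in pairs:
        if pid in used_pre or qid in used_post:
            continue
        used_pre.add(pid)
        used_post.add(qid)
        out.append((pid, qid))
    return out


def count_new_vesicles(pre: SpotSet, post: SpotSet,
                       match_radius_um: float = 0.5) -> int:
    """Vesicles visible only in the post image: |post| - |matched pairs|."""
    return len(post) - len(match_spots(pre, post, match_radius_um))


@dataclass(frozen=True)
class ColocResult:
    coloc_mean: float | None
    coloc_area_um2: float
    n_mask_pixels: int
    flagged: bool = False


def lysosomal_colocalization(
    receptor_img: ChannelImage,
    lysosome_mask: np.ndarray,
    roi_mask: np.ndarray | None = None,
) -> ColocResult:
    """Receptor intensity and area over the lysosome mask (optionally in an ROI)."""
    mask = np.asarray(lysosome_mask, dtype=bool)
    if mask.shape != receptor_img.shape:
        raise ValueError("mask and image must share one shape")
    if roi_mask is not None:
        mask = mask & np.asarray(roi_mask, dtype=bool)
    n = int(mask.sum())
    area = n * receptor_img.pixel_size_um ** 2
    if n == 0:
        return ColocResult(coloc_mean=None, coloc_area_um2=0.0,
                           n_mask_pixels=0, flagged=True)
    return ColocResult(coloc_mean=float(receptor_img.pixels[mask].mean()),
                       coloc_area_um2=float(area), n_mask_pixels=n)


def lysosome_mask_from_tracker(tracker_img: ChannelImage,
                               smoothing_sigma_um: float = 0.1) -> np.ndarray:
    """Threshold the Lysotracker channel (Otsu) into a lysosome mask."""
    mask, _ = threshold_mask(tracker_img, method="otsu",
                             smoothing_sigma_um=smoothing_sigma_um)
    return mask
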