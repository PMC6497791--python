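"""Puncta segmentation and synaptic/extrasynaptic intensity quantification.

Receptor and scaffold signal in fluorescence images of neurons forms
micron-scale puncta.  A punctum is called *synaptic* when it colocalizes
with a presynaptic GABAergic marker (GAD65) cluster; everything else on
the dendrite is extrasynaptic.  This module segments puncta by binary
thresholding, labels them against a marker channel, and partitions ROI
intensity into synaptic / extrasynaptic / background components such that
the decomposition is exactly conservative.

Thresholds default to Otsu's criterion (exhaustive between-class-variance
maximization over the unique intensity values) so analyses are
reproducible without interactive threshold picking; the chosen threshold
is always reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.draw import polygon2mask
from skimage.filters import gaussian
from skimage.measure import label as _cc_label
from skimage.measure import regionprops


class DegenerateHistogramError(ValueError):
    """Raised when Otsu thresholding is requested on a constant image."""


@dataclass(frozen=True)
class ChannelImage:
    """One channel of a calibrated 2D fluorescence image.

    Parameters
    ----------
    pixels : ndarray
        2D array of non-negative intensities (row, col).
    pixel_size_um : float
        Physical pixel pitch in micrometres per pixel.
    channel : str
        Channel label (e.g. ``"receptor"``, ``"gad65"``).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("ChannelImage.pixels must be 2D")
        if np.any(px < 0):
            raise ValueError("intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RoiSpec:
    """Region of interest: polygon vertices in 0-based pixel coordinates.

    ``role`` distinguishes whole-cell, soma, dendrite and extrasynaptic
    segment ROIs; dendrite segments default to the 10 um nominal length
    used for per-cell averaging.
    """

    role: str
    vertices: tuple[tuple[float, float], ...]
    nominal_length_um: float = 10.0

    VALID_ROLES = ("whole_cell", "soma", "dendrite_segment", "extrasynaptic_segment")

    def __post_init__(self) -> None:
        if self.role not in self.VALID_ROLES:
            raise ValueError(f"unknown ROI role {self.role!r}")
        if len(self.vertices) < 3:
            raise ValueError("ROI polygon needs at least 3 vertices")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize the polygon onto an image grid (row, col vertices)."""
        m = polygon2mask(shape, np.asarray(self.vertices, dtype=float))
        if not m.any():
            raise ValueError("ROI polygon rasterizes to an empty mask")
        return m


@dataclass
class Cluster:
    id: int
    pixel_index: np.ndarray        # (n, 2) row/col coordinates
    area_um2: float
    centroid: tuple[float, float]  # row, col in pixels
    channel_sum: dict[str, float]
    channel_mean: dict[str, float]
    synaptic: bool = False


@dataclass
class ClusterSet:
    """Segmented puncta with per-channel intensity summaries."""

    clusters: list[Cluster]
    shape: tuple[int, int]
    pixel_size_um: float
    threshold: float | None = None

    def __len__(self) -> int:
        return len(self.clusters)

    def label_image(self) -> np.ndarray:
        lab = np.zeros(self.shape, dtype=int)
        for c in self.clusters:
            lab[c.pixel_index[:, 0], c.pixel_index[:, 1]] = c.id
        return lab

    @property
    def n_synaptic(self) -> int:
        return sum(c.synaptic for c in self.clusters)


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu threshold by exhaustive between-class-variance maximization.

    Candidates are the unique intensity values; a candidate ``t`` splits
    pixels into ``{x < t}`` and ``{x >= t}``.  Returns the lowest candidate
    maximizing the between-class variance.  Exact for images with a modest
    number of distinct levels (no histogram binning).
    """
    v = np.asarray(values, dtype=float).ravel()
    uniq = np.unique(v)
    if uniq.size < 2:
        raise DegenerateHistogramError(
            "cannot threshold a constant image: degenerate histogram"
        )
    best_t, best_var = uniq[0], -np.inf
    n = v.size
    for t in uniq[1:]:  # t = uniq[0] puts everything in one class
        lo = v < t
        n_lo = lo.sum()
        w_lo = n_lo / n
        w_hi = 1.0 - w_lo
        mu_lo = v[lo].mean()
        mu_hi = v[~lo].mean()
        var_b = w_lo * w_hi * (mu_lo - mu_hi) ** 2
        if var_b > best_var + 1e-15:
            best_var, best_t = var_b, t
    return float(best_t)


def threshold_mask(
    img: ChannelImage,
    method: str = "otsu",
    fixed_value: float | None = None,
    smoothing_sigma_um: float = 0.0,
) -> tuple[np.ndarray, dict]:
    """Binary threshold of a (optionally smoothed) channel image.

    Returns ``(mask, meta)`` where ``meta`` records the threshold actually
    applied.  The mask is true where the smoothed intensity is >= the
    threshold.
    """
    if method not in ("otsu", "fixed"):
        raise ValueError(f"unknown threshold method {method!r}")
    if method == "fixed" and fixed_value is None:
        raise ValueError("method='fixed' requires fixed_value")

    px = img.pixels
    if smoothing_sigma_um > 0:
        px = gaussian(px, sigma=smoothing_sigma_um / img.pixel_size_um,
                      preserve_range=True)
    thr = float(fixed_value) if method == "fixed" else otsu_threshold(px)
    mask = px >= thr
    meta = {"method": method, "threshold": thr,
            "smoothing_sigma_um": smoothing_sigma_um}
    return mask, meta


def detect_clusters(
    mask: np.ndarray,
    img: ChannelImage | dict[str, ChannelImage],
    size_window_um2: tuple[float, float] = (0.0, 3.0),
    min_pixels: int = 1,
) -> ClusterSet:
    """Connected components (8-connectivity) of a binary mask, size-filtered.

    Components with area in ``(min, max]`` um^2 are kept (half-open on the
    left so a zero lower bound excludes nothing real; closed on the right
    per the 0-3 um size-exclusion window).  ``min_pixels=2`` additionally
    drops single-pixel specks, standing in for interactive single-pixel
    cleanup in the FRET workflow.  Per-channel sums and means are
    computed on the original, unsmoothed intensities.
    """
    channels = {img.channel or "ch0": img} if isinstance(img, ChannelImage) else dict(img)
    ref = next(iter(channels.values()))
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ref.shape:
        raise ValueError("mask and image shapes differ")
    for ci in channels.values():
        if ci.shape != ref.shape:
            raise ValueError("all channel images must share one shape")

    lo, hi = size_window_um2
    px_area = ref.pixel_size_um ** 2
    lab = _cc_label(mask, connectivity=2)
    clusters: list[Cluster] = []
    next_id = 1
    for rp in regionprops(lab):
        area = rp.num_pixels * px_area
        if rp.num_pixels < min_pixels or not (lo < area <= hi):
            continue
        coords = rp.coords
        sums = {name: float(ci.pixels[coords[:, 0], coords[:, 1]].sum())
                for name, ci in channels.items()}
        means = {name: s / rp.num_pixels for name, s in sums.items()}
        clusters.append(Cluster(
            id=next_id, pixel_index=coords, area_um2=float(area),
            centroid=tuple(rp.centroid), channel_sum=sums, channel_mean=means,
        ))
        next_id += 1
    return ClusterSet(clusters=clusters, shape=ref.shape,
                      pixel_size_um=ref.pixel_size_um)


def label_synaptic(
    receptor: ClusterSet,
    marker: ClusterSet,
    min_overlap_px: int = 1,
) -> ClusterSet:
    """Flag receptor clusters synaptic iff they overlap a marker cluster.

    Overlap is counted in shared pixels against the union of marker
    clusters; the default criterion is a single shared pixel.
    """
    if receptor.shape != marker.shape:
        raise ValueError("cluster sets derive from differently shaped images")
    marker_occ = np.zeros(marker.shape, dtype=bool)
    for c in marker.clusters:
        marker_occ[c.pixel_index[:, 0], c.pixel_index[:, 1]] = True
    for c in receptor.clusters:
        overlap = int(marker_occ[c.pixel_index[:, 0], c.pixel_index[:, 1]].sum())
        c.synaptic = overlap >= min_overlap_px
    return receptor


@dataclass(frozen=True)
class IntensityPartition:
    synaptic_sum: float
    extrasynaptic_sum: float
    total_sum: float
    background_total: float
    roi_pixel_count: int
    oversubtracted: bool = False


def partition_intensity(
    img: ChannelImage,
    roi: RoiSpec | np.ndarray,
    synaptic: ClusterSet,
    background: float,
) -> IntensityPartition:
    """Split ROI intensity into synaptic, extrasynaptic and background.

    The synaptic sum is the background-corrected intensity over synaptic
    cluster pixels inside the ROI; extrasynaptic signal is defined by
    subtraction, total ROI sum minus the per-pixel background over the
    ROI minus the synaptic sum, so
    ``synaptic + extrasynaptic + background_total == total`` exactly.
    A negative extrasynaptic value (over-subtraction) is retained but
    flagged.
    """
    if background < 0:
        raise ValueError("background must be non-negative")
    roi_mask = roi if isinstance(roi, np.ndarray) else roi.mask(img.shape)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    total = float(img.pixels[roi_mask].sum())
    n_roi = int(roi_mask.sum())
    background_total = background * n_roi

    syn = 0.0
    for c in synaptic.clusters:
        if not c.synaptic:
            continue
        rr, cc = c.pixel_index[:, 0], c.pixel_index[:, 1]
        inside = roi_mask[rr, cc]
        syn += float(img.pixels[rr[inside], cc[inside]].sum()
                     - background * inside.sum())

    extra = total - background_total - syn
    over = extra < 0
    if over:
        warnings.warn("extrasynaptic sum is negative (background over-subtraction)",
                      stacklevel=2)
    return IntensityPartition(
        synaptic_sum=syn, extrasynaptic_sum=extra, total_sum=total,
        background_total=background_total, roi_pixel_count=n_roi,
        oversubtracted=bool(over),
    )


def estimate_background(img: ChannelImage, clusters: ClusterSet,
                        roi_mask: np.ndarray | None = None) -> float:
    """Median intensity of (ROI) pixels outside all clusters."""
    occ = np.zeros(img.shape, dtype=bool)
    for c in clusters.clusters:
        occ[c.pixel_index[:, 0], c.pixel_index[:, 1]] = True
    sel = ~occ if roi_mask is None else (~occ & np.asarray(roi_mask, dtype=bool))
    if not sel.any():
        raise ValueError("no background pixels available")
    return float(np.median(img.pixels[sel]))


def summarize_cell(per_roi_values) -> float:
    """Cell-level summary: arithmetic mean over the per-ROI values.

    Cells, not ROIs, are the experimental unit downstream; each cell
    contributes the mean of its (typically three) dendritic ROIs.
    """
    vals = [float(v) for v in per_roi_values]
    if not vals:
        raise ValueError("summarize_cell requires at least one ROI value")
    return float(np.mean(vals))


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t-distribution."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_remove_outlier(values, alpha: float = 0.05):
    """Remove at most one outlier by the two-sided Grubbs test.

    Computes G = max|x - mean| / sd (sample sd) and removes the most
    deviant point if G exceeds the critical value at ``alpha``.  Never
    iterates: the paper's convention is a single-outlier removal.

    Returns ``(retained_values, removed)`` where ``removed`` is None when
    no point is rejected.
    """
    vals = np.asarray(list(values), dtype=float)
    n = vals.size
    if n < 3:
        raise ValueError("Grubbs test requires at least 3 values")
    sd = vals.std(ddof=1)
    if sd == 0:
        return list(vals), None
    dev = np.abs(vals - vals.mean())
    i = int(np.argmax(dev))
    g = dev[i] / sd
    if g > grubbs_critical_value(n, alpha):
        removed = float(vals[i])
        return list(np.delete(vals, i)), removed
    return list(vals), None
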