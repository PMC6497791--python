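"""Synthetic fluorescence scenes, kinetics and spectral counts with ground truth.

Every downstream stage of the pipeline is testable without microscope or
mass-spectrometer data: this module renders dendritic puncta scenes
(Gaussian-profile puncta, optional presynaptic-marker colocalization),
two-pool photobleach-recovery traces, donor-quenched FRET observations,
vesicle spot fields and overdispersed co-IP spectral-count tables, each
alongside the exact truth used to generate it.

Noise model for images: Poisson shot noise approximated as Gaussian with
variance proportional to signal (``poisson_scale``) plus additive Gaussian
read noise (``gaussian_sd``).  All generators are deterministic for a
fixed integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .puncta import ChannelImage

DEFAULT_PIXEL_SIZE_UM = 0.1

# post-bleach sampling: every 2 min over a 60 min time-lapse
DEFAULT_FRAP_TIMEPOINTS_MIN = tuple(range(0, 62, 2))


@dataclass(frozen=True)
class Punctum:
    """A single Gaussian punctum: position/size in micrometres."""
    x_um: float
    y_um: float
    peak: float
    sigma_um: float
    synaptic: bool = False


@dataclass
class SceneTruth:
    """Ground truth for one rendered scene."""

    puncta: list[Punctum]
    background_level: float = 10.0
    poisson_scale: float = 0.0
    gaussian_sd: float = 0.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    shape: tuple[int, int] = (128, 128)   # rows, cols
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        for p in self.puncta:
            if p.sigma_um <= 0:
                raise ValueError("punctum sigma must be positive")
            if p.peak <= self.background_level:
                raise ValueError("punctum peak must exceed the background level")

    def punctum_integral(self, p: Punctum) -> float:
        """Analytic integral of one punctum above background, in intensity*px."""
        return p.peak * 2.0 * np.pi * (p.sigma_um / self.pixel_size_um) ** 2

    def to_json(self) -> str:
        d = asdict(self)
        d["puncta"] = [asdict(p) for p in self.puncta]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneTruth":
        d = json.loads(text)
        d["puncta"] = [Punctum(**p) for p in d["puncta"]]
        d["shape"] = tuple(d["shape"])
        return cls(**d)


@dataclass
class KineticTruth:
    """Ground truth for kinetic / FRET / count simulations.

    ``k_exchange`` is the per-minute synaptic exchange rate of the
    two-pool recovery model; ``mobile_fraction`` the recoverable fraction;
    ``bleach_depth`` the fraction of pre-bleach fluorescence remaining at
    t0; ``fret_efficiency`` the donor-quenching FRET efficiency E.
    """

    k_exchange: float = 0.05
    mobile_fraction: float = 0.8
    bleach_depth: float = 0.2
    fret_efficiency: float = 0.2
    n_vesicles_pre: int = 5
    n_vesicles_post: int = 12
    planted_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_exchange < 0:
            raise ValueError("k_exchange must be >= 0")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must be in [0, 1]")
        if not 0.0 <= self.bleach_depth < 1.0:
            raise ValueError("bleach_depth must be in [0, 1)")
        if not 0.0 <= self.fret_efficiency < 1.0:
            raise ValueError("fret_efficiency E must be in [0, 1)")


def _apply_noise(ideal: np.ndarray, poisson_scale: float, gaussian_sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    if poisson_scale <= 0 and gaussian_sd <= 0:
        return ideal
    var = np.maximum(poisson_scale * ideal, 0.0) + gaussian_sd ** 2
    noisy = ideal + rng.standard_normal(ideal.shape) * np.sqrt(var)
    return np.clip(noisy, 0.0, None)


def render_channel(truth: SceneTruth, puncta: list[Punctum],
                   rng: np.random.Generator | None = None,
                   channel: str = "") -> ChannelImage:
    """Render one channel: background + Gaussian puncta (+ noise)."""
    rows, cols = truth.shape
    h_um = rows * truth.pixel_size_um
    w_um = cols * truth.pixel_size_um
    for i, p in enumerate(puncta):
        if not (0.0 <= p.x_um < w_um and 0.0 <= p.y_um < h_um):
            raise ValueError(
                f"punctum {i} at ({p.x_um:.2f}, {p.y_um:.2f}) um lies outside "
                f"the {w_um:.2f} x {h_um:.2f} um image extent"
            )
    # pixel-centre coordinates in um (half-open [i, i+1) pixel bins)
    yy = (np.arange(rows) + 0.5) * truth.pixel_size_um
    xx = (np.arange(cols) + 0.5) * truth.pixel_size_um
    ideal = np.full((rows, cols), float(truth.background_level))
    for p in puncta:
        gy = np.exp(-((yy - p.y_um) ** 2) / (2 * p.sigma_um ** 2))
        gx = np.exp(-((xx - p.x_um) ** 2) / (2 * p.sigma_um ** 2))
        ideal += p.peak * np.outer(gy, gx)
    if rng is not None:
        ideal = _apply_noise(ideal, truth.poisson_scale, truth.gaussian_sd, rng)
    return ChannelImage(pixels=ideal, pixel_size_um=truth.pixel_size_um,
                        channel=channel)


def make_dendrite_scene(
    truth: SceneTruth,
    channels: tuple[str, ...] = ("receptor", "marker"),
    marker_channel: str = "marker",
) -> tuple[dict[str, ChannelImage], SceneTruth]:
    """Render a multi-channel dendritic scene from ground truth.

    All puncta are rendered in every non-marker channel; synaptic puncta
    are co-rendered in the presynaptic-marker channel so that marker
    colocalization recovers the planted synaptic labels.  Noise is drawn
    per channel from a generator seeded with ``truth.seed``; identical
    truth yields byte-identical images.
    """
    if len(set(channels)) != len(channels):
        raise ValueError("channel names must be unique")
    rng = np.random.default_rng(truth.seed)
    out: dict[str, ChannelImage] = {}
    for name in channels:
        pl = [p for p in truth.puncta if p.synaptic] if name == marker_channel \
            else list(truth.puncta)
        out[name] = render_channel(truth, pl, rng=rng, channel=name)
    return out, truth


def frap_mean(t, pre_bleach: float, k: float, mobile: float,
              bleach_depth: float):
    """Noiseless two-pool recovery: f(t) = pre*(d + m*(1-d)*(1-e^{-kt}))."""
    t = np.asarray(t, dtype=float)
    return pre_bleach * (bleach_depth
                         + mobile * (1.0 - bleach_depth) * (1.0 - np.exp(-k * t)))


def simulate_frap(
    kin: KineticTruth,
    timepoints_min,
    pre_bleach: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> "FRAPTrace":
    """Simulate one post-bleach recovery trace on the given time grid."""
    from .frap import FRAPTrace  # local import avoids a cycle

    t = np.asarray(list(timepoints_min), dtype=float)
    if t.size == 0 or t[0] != 0:
        raise ValueError("timepoints must start at 0")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if pre_bleach <= 0:
        raise ValueError("pre_bleach must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    mean = frap_mean(t, pre_bleach, kin.k_exchange, kin.mobile_fraction,
                     kin.bleach_depth)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mean = mean + rng.standard_normal(t.size) * noise_sd
    return FRAPTrace(synapse_id=f"sim-{seed}", site="synaptic",
                     pre_bleach=pre_bleach,
                     t_min=t, intensity=np.asarray(mean, dtype=float))


DEFAULT_FRET_COUPLING = 0.5


def simulate_fret_pair(
    kin: KineticTruth,
    donor_true: float = 100.0,
    acceptor_true: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    coupling: float = DEFAULT_FRET_COUPLING,
    acceptor_bleached: bool = False,
    bleed_through: float = 0.0,
) -> tuple[float, float, float]:
    """One FRET observation: (donor channel, FRET channel, total acceptor).

    Donor quenching model for paired subunits within one receptor:
    observed donor = donor_true*(1-E); the FRET channel carries
    E*coupling*min(donor_true, acceptor_true) — transfer requires both an
    excitable donor and an acceptor, so quenching the donor (donor_true
    -> 0) extinguishes the FRET channel — plus an optional constant
    bleed-through term.  Total acceptor is measured under direct
    excitation.  Bleaching the acceptor zeroes acceptor_true and restores
    the donor to donor_true (dequenching).  With coupling <= 1 the FRET
    channel never exceeds the total-acceptor channel.
    """
    if donor_true < 0 or acceptor_true < 0:
        raise ValueError("true intensities must be >= 0")
    if not coupling <= 1.0:
        raise ValueError("coupling must be <= 1")
    e = kin.fret_efficiency
    if acceptor_bleached:
        acceptor_true = 0.0
        e_eff = 0.0
    else:
        e_eff = e
    donor_obs = donor_true * (1.0 - e_eff)
    fret_obs = e_eff * coupling * min(donor_true, acceptor_true) + bleed_through
    total_obs = acceptor_true
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        donor_obs, fret_obs, total_obs = (
            max(0.0, v + rng.standard_normal() * noise_sd)
            for v in (donor_obs, fret_obs, total_obs)
        )
    return float(donor_obs), float(fret_obs), float(total_obs)


def simulate_bleach_series(
    kin: KineticTruth,
    donor_true: float = 100.0,
    acceptor_true: float = 100.0,
    n_pre: int = 12,
    n_post: int = 24,
    noise_sd: float = 0.0,
    seed: int = 0,
    coupling: float = DEFAULT_FRET_COUPLING,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Acceptor-photobleach time course: (donor frames, fret frames, bleach_index)."""
    rng = np.random.default_rng(seed)
    donor, fret = [], []
    for i in range(n_pre + n_post):
        d, f, _ = simulate_fret_pair(
            kin, donor_true, acceptor_true, noise_sd=0.0,
            coupling=coupling, acceptor_bleached=(i >= n_pre))
        if noise_sd > 0:
            d = max(0.0, d + rng.standard_normal() * noise_sd)
            f = max(0.0, f + rng.standard_normal() * noise_sd)
        donor.append(d)
        fret.append(f)
    return np.array(donor), np.array(fret), n_pre


def simulate_vesicle_field(
    n_vesicles: int,
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    diameter_um: float = 0.75,
    peak: float = 400.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    min_sep_um: float = 2.0,
    positions_um: list[tuple[float, float]] | None = None,
) -> tuple[ChannelImage, list[tuple[float, float]]]:
    """Render non-overlapping circular vesicle spots; returns image + centres (x, y um)."""
    rng = np.random.default_rng(seed)
    h_um = shape[0] * pixel_size_um
    w_um = shape[1] * pixel_size_um
    margin = diameter_um
    if positions_um is None:
        centres: list[tuple[float, float]] = []
        attempts = 0
        while len(centres) < n_vesicles:
            attempts += 1
            if attempts > 100000:
                raise RuntimeError("could not place non-overlapping vesicles")
            x = rng.uniform(margin, w_um - margin)
            y = rng.uniform(margin, h_um - margin)
            if all((x - cx) ** 2 + (y - cy) ** 2 >= min_sep_um ** 2
                   for cx, cy in centres):
                centres.append((x, y))
    else:
        centres = list(positions_um)[:n_vesicles]
    sigma_um = diameter_um / 4.0  # FWHM ~ 0.59*diameter: compact bright core
    truth = SceneTruth(
        puncta=[Punctum(x_um=x, y_um=y, peak=peak, sigma_um=sigma_um)
                for x, y in centres],
        background_level=background, gaussian_sd=noise_sd,
        pixel_size_um=pixel_size_um, shape=shape, seed=seed,
    )
    img = render_channel(truth, truth.puncta,
                         rng=rng if noise_sd > 0 else None, channel="vesicles")
    return img, centres


def simulate_vesicle_pair(
    kin: KineticTruth,
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    noise_sd: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> tuple[ChannelImage, ChannelImage, list[tuple[float, float]]]:
    """Pre/post intracellular-reveal vesicle scene pair.

    The post image contains the ``n_vesicles_pre`` original spots plus
    ``n_vesicles_post - n_vesicles_pre`` newly revealed ones at fresh
    positions; the pre image shows only the originals.  Returns
    ``(pre_image, post_image, all_centres)`` with the first
    ``n_vesicles_pre`` centres shared.
    """
    if kin.n_vesicles_post < kin.n_vesicles_pre:
        raise ValueError("n_vesicles_post must be >= n_vesicles_pre")
    _, centres = simulate_vesicle_field(
        kin.n_vesicles_post, shape=shape, pixel_size_um=pixel_size_um,
        noise_sd=0.0, seed=seed, **kwargs)
    pre_img, _ = simulate_vesicle_field(
        kin.n_vesicles_pre, shape=shape, pixel_size_um=pixel_size_um,
        noise_sd=noise_sd, seed=seed,
        positions_um=centres[:kin.n_vesicles_pre], **kwargs)
    post_img, _ = simulate_vesicle_field(
        kin.n_vesicles_post, shape=shape, pixel_size_um=pixel_size_um,
        noise_sd=noise_sd, seed=seed + 1, positions_um=centres, **kwargs)
    return pre_img, post_img, centres


def simulate_spectral_counts(
    planted: dict[str, float],
    n_proteins: int = 400,
    samples: list[tuple[str, str]] | None = None,
    library_sizes: dict[str, float] | float = 1e4,
    igg_background: float = 0.05,
    dispersion: float = 0.3,
    seed: int = 0,
    baseline_log_sd: float = 1.0,
):
    """Overdispersed co-IP spectral-count table with planted DZP/V effects.

    Counts follow a gamma-Poisson (negative-binomial) mixture per protein
    and sample: mean = baseline proportion * library size * treatment
    effect, with ``dispersion`` the NB dispersion (var = mu +
    dispersion*mu^2).  ``library_sizes`` is the expected total spectrum
    count per sample (a scalar or a per-sample map).  IgG control samples
    get ``igg_background`` times the specific-IP mean.  Planted proteins
    carry the mapped DZP/V ratio; a planted ratio of ``inf`` gives a
    DZP-only (NF-V) pattern and ``0`` a vehicle-only (NF-DZP) pattern.
    Exclusive-unique-peptide counts are >= 1 wherever a protein is
    detected and grow with the count.

    Returns ``(SpectralCountTable, truth_frame)``.
    """
    from .interactome import SpectralCountTable

    if samples is None:
        samples = [("V1", "VEH"), ("V2", "VEH"), ("V3", "VEH"),
                   ("D1", "DZP"), ("D2", "DZP"), ("D3", "DZP"),
                   ("IgG1", "IgG")]
    groups = [g for _, g in samples]
    if groups.count("VEH") < 2 or groups.count("DZP") < 2 or groups.count("IgG") < 1:
        raise ValueError("need >=2 VEH, >=2 DZP and >=1 IgG samples")
    if not 0.0 <= igg_background < 1.0:
        raise ValueError("igg_background must be in [0, 1)")

    rng = np.random.default_rng(seed)
    names = [f"P{i:04d}" for i in range(n_proteins)]
    prop = np.exp(rng.normal(0.0, baseline_log_sd, n_proteins))
    prop /= prop.sum()
    if np.isscalar(library_sizes):
        lib = {sid: float(library_sizes) for sid, _ in samples}
    else:
        lib = {sid: float(library_sizes[sid]) for sid, _ in samples}

    counts = np.zeros((n_proteins, len(samples)))
    for i, name in enumerate(names):
        ratio = planted.get(name, 1.0)
        for j, (sid, grp) in enumerate(samples):
            mu = prop[i] * lib[sid]
            if grp == "DZP":
                if ratio == 0.0:
                    mu = 0.0
                elif np.isinf(ratio):
                    pass  # DZP keeps baseline; VEH will be zeroed
                else:
                    mu *= ratio
            elif grp == "VEH" and np.isinf(ratio):
                mu = 0.0
            elif grp == "IgG":
                mu *= igg_background
            if mu <= 0:
                counts[i, j] = 0.0
                continue
            if dispersion > 0:
                lam = rng.gamma(shape=1.0 / dispersion,
                                scale=mu * dispersion)
            else:
                lam = mu
            counts[i, j] = rng.poisson(lam)

    detected = counts > 0
    peptides = np.where(detected, 1 + rng.poisson(np.sqrt(counts)), 0)

    # guarantee every protein appears somewhere (table invariant)
    empty = ~detected.any(axis=1)
    if empty.any():
        j0 = [j for j, (_, g) in enumerate(samples) if g != "IgG"][0]
        counts[empty, j0] = 1
        peptides[empty, j0] = 1

    count_df = pd.DataFrame(counts, index=names,
                            columns=[sid for sid, _ in samples])
    pep_df = pd.DataFrame(peptides, index=names, columns=count_df.columns)
    meta = pd.DataFrame({"sample": [sid for sid, _ in samples],
                         "treatment": [g for _, g in samples]}).set_index("sample")
    truth = pd.DataFrame({
        "protein": names,
        "true_ratio": [planted.get(n, 1.0) for n in names],
        "planted": [n in planted for n in names],
    }).set_index("protein")
    table = SpectralCountTable(counts=count_df, unique_peptides=pep_df,
                               sample_meta=meta)
    return table, truth
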