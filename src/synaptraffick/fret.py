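"""Intersubunit FRET quantification with ordered restriction criteria.

FRET between a pH-sensitive-GFP donor on one receptor subunit and an RFP
acceptor on another reports assembled surface receptors at synapses.
Three images are acquired per cell: the donor channel (488 nm excitation,
green emission), the FRET channel (488 nm excitation, red emission) and
the total-acceptor channel (561 nm direct excitation).  Per-synapse
records are screened by four ordered restriction criteria:

1. at least 15 synapses measured per cell, else the whole cell is
   rejected;
2. FRET:total-acceptor sum-intensity ratio must be strictly < 1;
3. synaptic donor mean intensity of at least 500;
4. donor sum intensity limited to 300% of the average donor sum of the
   synapses surviving steps 2-3.

Acceptor photobleaching (donor dequenching) and pH-quench controls verify
that the FRET channel reports genuine, surface-dependent energy transfer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .puncta import ChannelImage, ClusterSet, threshold_mask


@dataclass
class FretSynapseRecord:
    synapse_id: int
    donor_sum: float
    donor_mean: float
    fret_sum: float
    total_acceptor_sum: float

    @property
    def fret_total_ratio(self) -> float:
        if self.total_acceptor_sum == 0:
            return np.inf
        return self.fret_sum / self.total_acceptor_sum


@dataclass
class FretCellResult:
    cell_id: str
    records: list[FretSynapseRecord]
    drop_counts: dict[str, int] = field(default_factory=dict)
    rejected: bool = False
    rejection_reason: str = ""

    @property
    def n_surviving(self) -> int:
        return len(self.records)


def measure_synapse_fret(
    donor_img: ChannelImage,
    fret_img: ChannelImage,
    total_img: ChannelImage,
    clusters: ClusterSet,
    donor_threshold: float | None = None,
    acceptor_threshold: float | None = None,
) -> tuple[list[FretSynapseRecord], int]:
    """Per-cluster donor/FRET/total sums for clusters carrying both signals.

    A cluster is measured only if it contains above-threshold donor signal
    and above-threshold total-acceptor signal; the FRET and total-acceptor
    binaries share one threshold value (identical threshold ranges for the
    two red-emission channels).  Sums and means come from the unsmoothed
    intensities.  Returns ``(records, n_dropped)``.
    """
    for im in (fret_img, total_img):
        if im.shape != donor_img.shape:
            raise ValueError("donor/fret/total images must share one shape")
    if donor_threshold is None:
        _, meta = threshold_mask(donor_img, method="otsu")
        donor_threshold = meta["threshold"]
    if acceptor_threshold is None:
        _, meta = threshold_mask(total_img, method="otsu")
        acceptor_threshold = meta["threshold"]

    records: list[FretSynapseRecord] = []
    dropped = 0
    for c in clusters.clusters:
        rr, cc = c.pixel_index[:, 0], c.pixel_index[:, 1]
        dpix = donor_img.pixels[rr, cc]
        tpix = total_img.pixels[rr, cc]
        if not (np.any(dpix >= donor_threshold)
                and np.any(tpix >= acceptor_threshold)):
            dropped += 1
            continue
        fpix = fret_img.pixels[rr, cc]
        records.append(FretSynapseRecord(
            synapse_id=c.id,
            donor_sum=float(dpix.sum()),
            donor_mean=float(dpix.mean()),
            fret_sum=float(fpix.sum()),
            total_acceptor_sum=float(tpix.sum()),
        ))
    return records, dropped


def apply_restriction_criteria(
    records: list[FretSynapseRecord],
    cell_id: str = "",
    donor_mean_floor: float = 500.0,
    donor_sum_cap_pct: float = 300.0,
    min_synapses: int = 15,
) -> FretCellResult:
    """Apply the four ordered restriction criteria to one cell's records.

    Criteria are applied strictly in order; criterion 4's reference
    average is the mean donor sum over the synapses surviving criteria
    2-3 within the same cell.  Boundary conventions: "at least" is
    inclusive (criteria 1, 3), ratio must be strictly < 1 (criterion 2),
    the 300% cap is inclusive (criterion 4).
    """
    drops = {"criterion_1_min_synapses": 0, "criterion_2_ratio": 0,
             "criterion_3_donor_floor": 0, "criterion_4_sum_cap": 0}
    if len(records) < min_synapses:
        drops["criterion_1_min_synapses"] = len(records)
        return FretCellResult(
            cell_id=cell_id, records=[], drop_counts=drops, rejected=True,
            rejection_reason=f"fewer than {min_synapses} synapses measured",
        )
    keep = [r for r in records if r.fret_total_ratio < 1.0]
    drops["criterion_2_ratio"] = len(records) - len(keep)

    keep2 = [r for r in keep if r.donor_mean >= donor_mean_floor]
    drops["criterion_3_donor_floor"] = len(keep) - len(keep2)

    if keep2:
        mean_sum = float(np.mean([r.donor_sum for r in keep2]))
        cap = donor_sum_cap_pct / 100.0 * mean_sum
        keep3 = [r for r in keep2 if r.donor_sum <= cap]
        drops["criterion_4_sum_cap"] = len(keep2) - len(keep3)
    else:
        keep3 = []

    res = FretCellResult(cell_id=cell_id, records=keep3, drop_counts=drops)
    if not keep3:
        res.rejected = True
        res.rejection_reason = "no valid synapses"
    return res


def fret_participation(result: FretCellResult) -> float:
    """Fraction of acceptor participating in FRET: sum(FRET)/sum(total)."""
    if not result.records:
        raise ValueError("no surviving synapses")
    fret = sum(r.fret_sum for r in result.records)
    total = sum(r.total_acceptor_sum for r in result.records)
    if total == 0:
        raise ValueError("zero total acceptor intensity")
    return fret / total


@dataclass
class BleachReport:
    donor_dequench_pct: float
    fret_change_pct: float
    efficiency_estimate: float
    ratio_trajectory: np.ndarray
    incomplete_bleach: bool


def acceptor_bleach_timecourse(
    donor_series,
    fret_series,
    bleach_index: int,
    background: float = 0.0,
) -> BleachReport:
    """Donor dequenching analysis of an acceptor-photobleach time course.

    Frames before ``bleach_index`` are pre-bleach.  Reports the percent
    change in background-subtracted donor intensity, the donor/FRET ratio
    trajectory, and the FRET efficiency estimate
    E_hat = 1 - mean(pre donor)/mean(post donor).  If the FRET channel is
    not reduced by >= 50% post bleach the result is flagged as an
    incomplete bleach.
    """
    donor = np.asarray(donor_series, dtype=float) - background
    fret = np.asarray(fret_series, dtype=float) - background
    if donor.size != fret.size:
        raise ValueError("donor and fret series lengths differ")
    if not 2 <= bleach_index < donor.size:
        raise ValueError("need >= 2 pre-bleach frames and a post-bleach phase")
    pre_d = donor[:bleach_index].mean()
    post_d = donor[bleach_index:].mean()
    pre_f = fret[:bleach_index].mean()
    post_f = fret[bleach_index:].mean()
    if pre_d <= 0 or post_d <= 0:
        raise ValueError("non-positive donor intensity after background subtraction")
    dequench = (post_d - pre_d) / pre_d * 100.0
    fret_change = (post_f - pre_f) / pre_f * 100.0 if pre_f > 0 else 0.0
    e_hat = 1.0 - pre_d / post_d
    incomplete = pre_f > 0 and post_f > 0.5 * pre_f
    if incomplete:
        warnings.warn("incomplete bleach: FRET channel not reduced by >= 50%",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fret > 0, donor / fret, np.nan)
    return BleachReport(
        donor_dequench_pct=float(dequench),
        fret_change_pct=float(fret_change),
        efficiency_estimate=float(e_hat),
        ratio_trajectory=ratio,
        incomplete_bleach=bool(incomplete),
    )


def ph_quench_control(hbs_frames, mes_frames) -> float:
    """Normalized FRET-channel change under acidic donor quench.

    Mean FRET intensity under MES (pH 6.0, donor quenched) divided by the
    mean under HBS (pH 7.4).  A surface-dependent FRET signal collapses
    toward 0; pure bleed-through stays near 1.
    """
    hbs = np.asarray(list(hbs_frames), dtype=float)
    mes = np.asarray(list(mes_frames), dtype=float)
    if hbs.size == 0 or mes.size == 0:
        raise ValueError("need >= 1 frame per condition")
    if hbs.mean() == 0:
        raise ValueError("zero HBS mean intensity")
    return float(mes.mean() / hbs.mean())


def normalize_to_control(values, control_mean: float) -> np.ndarray:
    """Express values as percent of a control-cohort mean (reporting only)."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return np.asarray(values, dtype=float) / control_mean * 100.0
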