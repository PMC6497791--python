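"""FRAP recovery normalization, averaging, kinetics and group comparison.

Per-synapse post-bleach traces are first normalized to pre-bleach
fluorescence and then expressed as percent of the first post-bleach frame,
r(t) = (I(t)/I(0)) * 100, which is the reporting scale used throughout the
recovery figures.  Because that scale can exceed 100% and diverges as
I(0) -> 0, kinetic fitting is performed on the pre-bleach fraction scale
I(t)/pre_bleach using a two-pool single-exponential exchange model

    f(t) = d + m * (1 - d) * (1 - exp(-k t))

with bleach depth d, mobile fraction m and exchange rate k (per minute).
Group comparison uses a two-factor (treatment x time) fixed-effects ANOVA
with per-timepoint Tukey HSD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class FRAPTrace:
    """Per-synapse pre/post-bleach intensity time series (minutes)."""

    synapse_id: str
    site: str                      # "synaptic" or "extrasynaptic"
    pre_bleach: float
    t_min: np.ndarray
    intensity: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t_min.size != self.intensity.size:
            raise ValueError("time and intensity lengths differ")
        if self.t_min.size == 0 or self.t_min[0] != 0:
            raise ValueError("trace must start at t = 0")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.pre_bleach > 0:
            raise ValueError("pre_bleach must be positive")


@dataclass
class NormalizedRecovery:
    """Recovery on the percent-of-t0 scale; value at t = 0 is exactly 100."""

    t_min: np.ndarray
    percent_of_t0: np.ndarray
    synapse_id: str = ""

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.percent_of_t0 = np.asarray(self.percent_of_t0, dtype=float)


class UnusableBaselineError(ValueError):
    """Raised when the first post-bleach intensity is not positive."""


def normalize_trace(trace: FRAPTrace) -> NormalizedRecovery:
    """Normalize to pre-bleach, then express as percent of t0.

    r(t) = [(I(t)/pre) / (I(0)/pre)] * 100 = (I(t)/I(0)) * 100; the
    pre-bleach factors cancel, so the result is invariant to any positive
    rescaling of the raw intensities.
    """
    i0 = trace.intensity[0]
    if i0 <= 0:
        raise UnusableBaselineError(
            f"trace {trace.synapse_id}: unusable bleach baseline (I(0) <= 0)")
    return NormalizedRecovery(
        t_min=trace.t_min.copy(),
        percent_of_t0=trace.intensity / i0 * 100.0,
        synapse_id=trace.synapse_id,
    )


def average_recovery(traces: list[NormalizedRecovery]):
    """Pointwise mean and SEM of recoveries sharing one time grid.

    Returns ``(mean, sem, n)`` arrays over the common grid.  Traces on
    mismatched grids are rejected rather than interpolated.
    """
    if not traces:
        raise ValueError("no traces to average")
    grid = traces[0].t_min
    for tr in traces[1:]:
        if tr.t_min.shape != grid.shape or not np.array_equal(tr.t_min, grid):
            raise ValueError("traces do not share a common time grid")
    mat = np.vstack([tr.percent_of_t0 for tr in traces])
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(grid.size)
    return mean, sem, n


@dataclass
class ExchangeFit:
    k_exchange: float | None
    mobile_fraction: float | None
    bleach_depth: float | None
    residual_norm: float
    converged: bool
    n_points: int


def _twopool(t, k, m, d):
    return d + m * (1.0 - d) * (1.0 - np.exp(-k * t))


def fit_exchange(trace) -> ExchangeFit:
    """Least-squares fit of the two-pool model on the pre-bleach scale.

    Accepts a single :class:`FRAPTrace`, a list of traces (pooled fit over
    all points), or a :class:`NormalizedRecovery`.  For a normalized curve
    the pre-bleach level is unknown, so only k and the recovery amplitude
    a = m(1-d)/d are identifiable; the mobile fraction is reported missing.
    Bounds: k >= 0, 0 <= m <= 1, 0 <= d < 1.  Initial values come from
    the data (d from the first frame, m from the late plateau).  A failed
    fit is returned flagged with parameters missing, never raised.
    """
    if isinstance(trace, NormalizedRecovery):
        return _fit_normalized(trace)
    traces = trace if isinstance(trace, (list, tuple)) else [trace]
    t = np.concatenate([tr.t_min for tr in traces])
    if np.unique(t).size < 5:
        raise ValueError("fit requires at least 5 timepoints")
    y = np.concatenate([tr.intensity / tr.pre_bleach for tr in traces])
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    d0 = float(np.clip(y[0], 0.0, 0.99))
    plateau = float(np.clip(np.mean(y[-max(2, t.size // 5):]), d0 + 1e-6, 1.0))
    m0 = float(np.clip((plateau - d0) / max(1e-9, 1.0 - d0), 1e-3, 1.0))
    span = t[-1] if t[-1] > 0 else 1.0
    try:
        popt, _ = optimize.curve_fit(
            _twopool, t, y, p0=[1.0 / span, m0, d0],
            bounds=([0.0, 0.0, 0.0], [np.inf, 1.0, 1.0 - 1e-9]),
            maxfev=10000,
        )
        resid = float(np.linalg.norm(_twopool(t, *popt) - y))
        k, m, d = (float(v) for v in popt)
        # a flat trace leaves k unidentified along the k*m ~ 0 ridge:
        # report the k = 0 boundary when the fitted recovery amplitude
        # is negligible
        if m * (1.0 - d) * (1.0 - np.exp(-k * t[-1])) < 1e-6:
            k, m = 0.0, 0.0
        return ExchangeFit(k_exchange=k, mobile_fraction=m, bleach_depth=d,
                           residual_norm=resid, converged=True,
                           n_points=t.size)
    except RuntimeError:
        return ExchangeFit(k_exchange=None, mobile_fraction=None,
                           bleach_depth=None, residual_norm=np.inf,
                           converged=False, n_points=t.size)


def _fit_normalized(curve: NormalizedRecovery) -> ExchangeFit:
    t = curve.t_min
    if t.size < 5:
        raise ValueError("fit requires at least 5 timepoints")
    y = curve.percent_of_t0 / 100.0

    def model(tt, k, a):
        return 1.0 + a * (1.0 - np.exp(-k * tt))

    a0 = max(1e-3, float(y[-1] - 1.0))
    span = t[-1] if t[-1] > 0 else 1.0
    try:
        popt, _ = optimize.curve_fit(model, t, y, p0=[1.0 / span, a0],
                                     bounds=([0.0, 0.0], [np.inf, np.inf]),
                                     maxfev=10000)
        resid = float(np.linalg.norm(model(t, *popt) - y))
        return ExchangeFit(k_exchange=float(popt[0]), mobile_fraction=None,
                           bleach_depth=None, residual_norm=resid,
                           converged=True, n_points=t.size)
    except RuntimeError:
        return ExchangeFit(k_exchange=None, mobile_fraction=None,
                           bleach_depth=None, residual_norm=np.inf,
                           converged=False, n_points=t.size)


# ---------------------------------------------------------------------------
# two-factor fixed-effects ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

@dataclass
class AnovaReport:
    f_treatment: float
    p_treatment: float
    df_treatment: tuple[int, int]
    f_time: float
    p_time: float
    df_time: tuple[int, int]
    f_interaction: float
    p_interaction: float
    df_interaction: tuple[int, int]
    tukey: pd.DataFrame = field(repr=False, default=None)


def two_way_anova(values: np.ndarray, factor_a, factor_b) -> dict:
    """Classical two-factor fixed-effects ANOVA with replication.

    Cell means / marginal means decomposition; exact for balanced
    designs, with unbalanced cells handled by the unweighted-means
    approximation (harmonic-mean cell size).
    """
    values = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    a_levels = list(dict.fromkeys(fa.tolist()))
    b_levels = list(dict.fromkeys(fb.tolist()))
    a, b = len(a_levels), len(b_levels)
    cell_means = np.zeros((a, b))
    cell_n = np.zeros((a, b))
    ss_within = 0.0
    for i, al in enumerate(a_levels):
        for j, bl in enumerate(b_levels):
            sel = (fa == al) & (fb == bl)
            v = values[sel]
            if v.size == 0:
                raise ValueError("singular design: empty treatment x time cell")
            cell_means[i, j] = v.mean()
            cell_n[i, j] = v.size
            ss_within += float(((v - v.mean()) ** 2).sum())
    n_h = cell_means.size / (1.0 / cell_n).sum()   # harmonic mean cell size
    grand = cell_means.mean()
    mean_a = cell_means.mean(axis=1)
    mean_b = cell_means.mean(axis=0)
    ss_a = n_h * b * float(((mean_a - grand) ** 2).sum())
    ss_b = n_h * a * float(((mean_b - grand) ** 2).sum())
    inter = cell_means - mean_a[:, None] - mean_b[None, :] + grand
    ss_ab = n_h * float((inter ** 2).sum())
    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_w = int(values.size - a * b)
    if df_w <= 0:
        raise ValueError("singular design: no within-cell replication")
    ms_w = ss_within / df_w

    def ftest(ss, df):
        if df == 0:
            return np.nan, np.nan
        f = (ss / df) / ms_w if ms_w > 0 else 0.0
        return f, float(stats.f.sf(f, df, df_w)) if ms_w > 0 else 1.0

    f_a, p_a = ftest(ss_a, df_a)
    f_b, p_b = ftest(ss_b, df_b)
    f_ab, p_ab = ftest(ss_ab, df_ab)
    return {
        "treatment": (f_a, p_a, (df_a, df_w)),
        "time": (f_b, p_b, (df_b, df_w)),
        "interaction": (f_ab, p_ab, (df_ab, df_w)),
        "ms_within": ms_w, "df_within": df_w,
        "cell_means": cell_means, "cell_n": cell_n,
        "a_levels": a_levels, "b_levels": b_levels,
    }


def tukey_hsd_per_timepoint(res: dict) -> pd.DataFrame:
    """Tukey HSD between treatment groups at each timepoint.

    Uses the pooled within-cell mean square and the studentized-range
    distribution with k = number of treatments; unbalanced cells use the
    harmonic mean of the two cell sizes.
    """
    ms_w, df_w = res["ms_within"], res["df_within"]
    k = len(res["a_levels"])
    rows = []
    for j, tl in enumerate(res["b_levels"]):
        for i1, i2 in itertools.combinations(range(k), 2):
            m1, m2 = res["cell_means"][i1, j], res["cell_means"][i2, j]
            n1, n2 = res["cell_n"][i1, j], res["cell_n"][i2, j]
            n_h = 2.0 / (1.0 / n1 + 1.0 / n2)
            se = np.sqrt(ms_w / n_h)
            q = abs(m1 - m2) / se if se > 0 else 0.0
            p_adj = float(stats.studentized_range.sf(q, k, df_w)) if se > 0 else 1.0
            rows.append({"t_min": tl,
                         "group1": res["a_levels"][i1],
                         "group2": res["a_levels"][i2],
                         "mean_diff": m1 - m2, "q": q,
                         "p_adj": min(1.0, p_adj)})
    return pd.DataFrame(rows)


def compare_groups(groups: dict[str, list[NormalizedRecovery]]) -> AnovaReport:
    """Two-factor (treatment x time) ANOVA + per-timepoint Tukey HSD.

    ``groups`` maps treatment label to its normalized recoveries; all
    traces must share one time grid and every group needs >= 2 traces.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    grid = None
    vals, f_treat, f_time = [], [], []
    for name, traces in groups.items():
        if len(traces) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 traces")
        for tr in traces:
            if grid is None:
                grid = tr.t_min
            elif not np.array_equal(tr.t_min, grid):
                raise ValueError("traces do not share a common time grid")
            vals.extend(tr.percent_of_t0.tolist())
            f_treat.extend([name] * tr.t_min.size)
            f_time.extend(tr.t_min.tolist())
    res = two_way_anova(np.array(vals), np.array(f_treat), np.array(f_time))
    tukey = tukey_hsd_per_timepoint(res)
    return AnovaReport(
        f_treatment=res["treatment"][0], p_treatment=res["treatment"][1],
        df_treatment=res["treatment"][2],
        f_time=res["time"][0], p_time=res["time"][1], df_time=res["time"][2],
        f_interaction=res["interaction"][0], p_interaction=res["interaction"][1],
        df_interaction=res["interaction"][2],
        tukey=tukey,
    )


def traces_from_frame(df: pd.DataFrame) -> list[FRAPTrace]:
    """Build traces from long-format columns (synapse_id, site, t_min, intensity, pre_bleach)."""
    out = []
    for sid, sub in df.groupby("synapse_id", sort=True):
        sub = sub.sort_values("t_min")
        out.append(FRAPTrace(
            synapse_id=str(sid), site=str(sub["site"].iloc[0]),
            pre_bleach=float(sub["pre_bleach"].iloc[0]),
            t_min=sub["t_min"].to_numpy(), intensity=sub["intensity"].to_numpy(),
        ))
    return out
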