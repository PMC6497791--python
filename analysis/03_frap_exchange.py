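#!/usr/bin/env python
"""Simulate vehicle- and DZP-like FRAP cohorts (slow vs fast synaptic
exchange), normalize each trace to percent-of-t0, fit the two-pool
exchange model per synapse, and compare the cohorts by two-factor ANOVA
with per-timepoint Tukey HSD.

Finding: with 60 synapses per cohort and 5% measurement noise the median
fitted exchange rate lands within a few percent of the generating truth
for both cohorts, and the treatment effect is detected at adjusted
p << 0.05, mirroring an accelerated-recovery phenotype."""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from synaptraffick.frap import compare_groups, fit_exchange, normalize_trace
from synaptraffick.scenes import (
    DEFAULT_FRAP_TIMEPOINTS_MIN,
    KineticTruth,
    simulate_frap,
)

ROOT = Path(__file__).resolve().parents[1]
CONDITIONS = {"vehicle": 0.02, "dzp": 0.06}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-traces", type=int, default=60)
    ap.add_argument("--outdir", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    t = list(DEFAULT_FRAP_TIMEPOINTS_MIN)
    rows, groups = [], {}
    for name, k in CONDITIONS.items():
        kin = KineticTruth(k_exchange=k, mobile_fraction=0.8, bleach_depth=0.2)
        off = args.seed + (0 if name == "vehicle" else 50_000)
        traces = [simulate_frap(kin, t, 100.0, 5.0, seed=off + i)
                  for i in range(args.n_traces)]
        groups[name] = [normalize_trace(tr) for tr in traces]
        for tr in traces:
            fit = fit_exchange(tr)
            rows.append({"condition": name, "true_k": k,
                         "k_exchange": fit.k_exchange,
                         "mobile_fraction": fit.mobile_fraction,
                         "converged": fit.converged})
    fits = pd.DataFrame(rows)
    fits.to_csv(args.outdir / "frap_fits.csv", index=False)

    report = compare_groups(groups)
    report.tukey.to_csv(args.outdir / "frap_tukey.csv", index=False)
    (args.outdir / "frap_anova.json").write_text(json.dumps({
        "f_treatment": report.f_treatment, "p_treatment": report.p_treatment,
        "f_time": report.f_time, "p_time": report.p_time,
        "f_interaction": report.f_interaction,
        "p_interaction": report.p_interaction}, indent=2))

    for name, k in CONDITIONS.items():
        med = fits.loc[fits.condition == name, "k_exchange"].median()
        print(f"{name}: true k {k}/min, median fitted k {med:.4f} "
              f"({abs(med - k) / k * 100:.1f}% error)")
    print(f"treatment F = {report.f_treatment:.1f}, "
          f"p = {report.p_treatment:.2e}; "
          f"min Tukey-adjusted p = {report.tukey['p_adj'].min():.2e}")


if __name__ == "__main__":
    main()
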