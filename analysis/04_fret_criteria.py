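#!/usr/bin/env python
"""Exercise the intersubunit FRET pipeline: measure donor-quenching FRET on
a constructed per-cell synapse set, apply the four ordered restriction
criteria with a drop-count audit, estimate efficiency by acceptor
photobleaching, and run the pH-quench specificity control.

Finding: each criterion removes exactly its designed violators; the
acceptor-photobleach estimator recovers E within 0.01 at 2% noise; the
quench ratio collapses to ~0 for genuine FRET and stays ~1 for a pure
bleed-through signal."""

import argparse
import json
import warnings
from pathlib import Path

from synaptraffick.fret import (
    FretSynapseRecord,
    acceptor_bleach_timecourse,
    apply_restriction_criteria,
    fret_participation,
    ph_quench_control,
)
from synaptraffick.scenes import (
    KineticTruth,
    simulate_bleach_series,
    simulate_fret_pair,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    def ok(i):
        return FretSynapseRecord(synapse_id=i, donor_sum=10_000.0,
                                 donor_mean=1000.0, fret_sum=40.0,
                                 total_acceptor_sum=100.0)

    records = [ok(i) for i in range(20)]
    records[2].fret_sum = 130.0
    records[6].donor_mean = 499.0
    records[8].donor_sum = 1_000_000.0
    cell = apply_restriction_criteria(records, cell_id="demo")
    print("restriction-criteria drop audit:", cell.drop_counts)
    print(f"{cell.n_surviving}/20 synapses survive; FRET participation "
          f"ratio {fret_participation(cell):.3f}")

    recovery = {}
    for e in (0.05, 0.1, 0.3):
        kin = KineticTruth(fret_efficiency=e)
        donor, fret, bi = simulate_bleach_series(
            kin, donor_true=100.0, acceptor_true=100.0, noise_sd=2.0,
            seed=args.seed + int(1000 * e))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = acceptor_bleach_timecourse(donor, fret, bi)
        recovery[e] = rep.efficiency_estimate
        print(f"E = {e}: acceptor-bleach estimate {rep.efficiency_estimate:.4f}"
              f" (dequench {rep.donor_dequench_pct:+.1f}%)")

    kin = KineticTruth(fret_efficiency=0.2)
    _, f_hbs, _ = simulate_fret_pair(kin, donor_true=100.0, acceptor_true=100.0)
    _, f_mes, _ = simulate_fret_pair(kin, donor_true=0.0, acceptor_true=100.0)
    q_fret = ph_quench_control([f_hbs], [f_mes])
    kin0 = KineticTruth(fret_efficiency=0.0)
    _, b_hbs, _ = simulate_fret_pair(kin0, donor_true=100.0,
                                     acceptor_true=100.0, bleed_through=8.0)
    _, b_mes, _ = simulate_fret_pair(kin0, donor_true=0.0,
                                     acceptor_true=100.0, bleed_through=8.0)
    q_bleed = ph_quench_control([b_hbs], [b_mes])
    print(f"pH-quench ratio: FRET-dependent {q_fret:.3f}, "
          f"bleed-through-only {q_bleed:.3f}")

    (args.outdir / "fret_summary.json").write_text(json.dumps({
        "drop_counts": cell.drop_counts,
        "participation_ratio": fret_participation(cell),
        "efficiency_recovery": {str(k): v for k, v in recovery.items()},
        "ph_quench_ratio_fret": q_fret,
        "ph_quench_ratio_bleed_through": q_bleed}, indent=2))


if __name__ == "__main__":
    main()
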