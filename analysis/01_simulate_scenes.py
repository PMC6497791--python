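#!/usr/bin/env python
"""Generate the synthetic study inputs: a two-channel dendrite scene with
ground truth, FRAP/FRET simulator parameter files and the packaged
association-table fixture.  Everything downstream analyses consume lives
under results/simulated/."""

import argparse
from pathlib import Path

from synaptraffick.cli import build_fixtures

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path,
                    default=ROOT / "results" / "simulated")
    args = ap.parse_args()
    written = build_fixtures(args.outdir, seed=args.seed)
    print(f"wrote {len(written)} files to {args.outdir}:")
    for p in written:
        print("  -", p.name)


if __name__ == "__main__":
    main()
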