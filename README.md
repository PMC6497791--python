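# synaptraffick

Quantification pipeline for studies of GABA<sub>A</sub> receptor and
gephyrin trafficking at inhibitory synapses — the kind of experiment in
which cultured neurons expressing tagged γ2/α2 receptor subunits are
treated with a benzodiazepine such as diazepam (DZP) and the response is
read out by fluorescence microscopy and co-immunoprecipitation
proteomics.

The package implements, as tested and reusable code, the five
quantification procedures such studies rely on:

1. **Puncta quantification** — binary-threshold segmentation of receptor
   and scaffold puncta, synaptic labeling by colocalization with a
   presynaptic GABAergic marker (GAD65), and an exactly conservative
   partition of dendritic ROI intensity into synaptic, extrasynaptic and
   background components, with cell-level averaging over 10 μm dendrite
   ROIs and a single-outlier Grubbs rule (α = 0.05).
2. **FRAP exchange kinetics** — per-synapse post-bleach traces normalized
   to pre-bleach and then to percent of t0, r(t) = (I(t)/I(0))·100;
   two-pool single-exponential exchange model
   f(t) = d + m(1−d)(1−e<sup>−kt</sup>) fitted on the pre-bleach scale;
   cohort comparison by two-factor (treatment × time) fixed-effects ANOVA
   with per-timepoint Tukey HSD.
3. **Intersubunit FRET** — donor-quenching FRET between pHluorin-tagged
   α2 (donor) and RFP-tagged γ2 (acceptor) subunits; four ordered
   restriction criteria (≥15 synapses/cell; FRET:total-acceptor sum ratio
   < 1; donor mean ≥ 500; donor sum ≤ 300% of the surviving-synapse
   average) with a per-criterion drop audit; FRET efficiency from
   acceptor photobleaching, Ê = 1 − donor<sub>pre</sub>/donor<sub>post</sub>;
   pH-quench (MES) specificity control.
4. **Vesicle/lysosome trafficking** — surface/total receptor ratio from
   the NH₄Cl intracellular-reveal assay, stringent circular-spot
   detection of ~0.75 μm vesicles, new-vesicle counting by greedy
   nearest-neighbour matching of pre/post spot sets, and receptor
   intensity/area scoring over a Lysotracker-derived lysosome mask.
5. **Co-IP interactome** — spectral-count inclusion filtering (≥2 unique
   peptides; detected in ≥3 samples overall or 2-of-3 in one group;
   ≥3:1 enrichment over the IgG control), DZP/vehicle abundance ratios
   with Student's t-tests and NF-V/NF-DZP sentinel classes, the
   pathway-input fold-change conversion (−1/x for ratios in (0, 1),
   ±1E+99 for NF classes), and a generic Fisher-exact overrepresentation
   test with Bonferroni correction.

A synthetic-data module generates every input with recorded ground
truth — Gaussian-profile puncta scenes, two-pool recovery traces,
donor-quenched FRET observations, vesicle spot fields and
negative-binomial spectral-count tables — so every stage is testable
without microscope or mass-spectrometer data. A transcription of the
published DZP/vehicle association tables (69 proteins) ships with the
package as a worked fixture.

## Worked example

Classify the packaged association tables and run a FRAP cohort
comparison:

```bash
$ synaptraffick --outdir out interactome
increased 46 (NF-V 10), decreased 23 (NF-DZP 7)

$ python analysis/03_frap_exchange.py
vehicle: true k 0.02/min, median fitted k 0.0196 (1.9% error)
dzp: true k 0.06/min, median fitted k 0.0620 (3.3% error)
treatment F = 1498.7, p = 4.30e-275; min Tukey-adjusted p = 0.00e+00
```

The first command reproduces the published interactome classification:
46 proteins with increased γ2 association after DZP (10 of them found in
no vehicle sample) and 23 with decreased association (7 found in no DZP
sample). The second simulates 60 noisy synaptic recovery traces per
condition at the generator's slow (vehicle-like, k = 0.02/min) and fast
(DZP-like, k = 0.06/min) exchange rates, fits the two-pool model per
synapse, and detects the treatment effect — the accelerated-exchange
phenotype — with the two-factor ANOVA.

The numbered scripts under `analysis/` walk through all five procedures
in order (`01_simulate_scenes.py` … `06_interactome.py`); each prints
what it found and writes its tables under `results/`.

## Command-line interface

`synaptraffick` exposes subcommands `simulate`, `puncta`, `frap`,
`fret`, `vesicles`, `lyso`, `interactome` and `fixtures`, with global
`--seed`, `--outdir`, `--config` (YAML) and `--log-level` flags. Every
stage writes a `manifest.json` with input hashes, parameters, seed and
version; deterministic stages reproduce byte-identical outputs from the
same configuration.

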