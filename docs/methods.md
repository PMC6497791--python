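# Methods

This note documents the models, parameter choices and numerical
conventions behind each stage of the pipeline, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Synthetic scenes and noise model

Images are rendered on a 0-based pixel grid (origin top-left, half-open
[i, i+1) pixel bins, intensities evaluated at pixel centres) with a
default pixel pitch of 0.1 μm — typical of a 60× confocal acquisition at
high zoom. Each punctum is an isotropic 2D Gaussian with peak amplitude
above a constant background; its analytic integral above background is
`peak · 2πσ²` in intensity·pixels, which the partition tests use as
ground truth. Synaptic puncta are co-rendered in the presynaptic-marker
channel so marker colocalization recovers the planted labels exactly.

Noise follows confocal statistics approximated without a Poisson draw:
variance = `poisson_scale · signal + gaussian_sd²`, i.e. signal-
proportional shot noise plus additive read noise, applied as Gaussian
and clipped at zero. All generators are driven by
`numpy.random.default_rng(seed)`, so a fixed integer seed gives
byte-identical output across runs and platforms.

What the scenes do **not** emulate: optical point-spread physics beyond
the Gaussian profile, 3D structure, dendrite morphology, uneven
illumination, photobleaching during acquisition, or spatially correlated
background. Passing tests therefore demonstrate correctness of the
measurement procedures under idealized imaging, not robustness to every
artifact of real microscopy.

## Puncta quantification

* **Thresholding.** Interactive threshold picking is replaced by Otsu's
  criterion computed as an exhaustive between-class-variance
  maximization over the unique intensity values (no histogram binning),
  with a fixed-value override; the chosen threshold is always reported
  in the result metadata. Mask convention: smoothed intensity ≥
  threshold; ties resolve to the lowest maximizing threshold. A constant
  image raises a degenerate-histogram error rather than returning an
  arbitrary mask.
* **Clusters.** 8-connected components, size-filtered to the
  (0, 3] μm² window used for synaptic cluster size exclusion; sums and
  means are always taken from the original unsmoothed intensities. A
  minimum cluster size of 2 pixels stands in for interactive single-pixel
  cleanup when enabled by the size window's lower bound.
* **Synaptic labeling.** A receptor cluster is synaptic iff it shares at
  least `min_overlap_px` pixels (default 1) with any marker cluster —
  colocalization is not quantified more finely than pixel overlap.
* **Intensity partition.** The synaptic sum is the background-corrected
  intensity over synaptic-cluster pixels inside the ROI; extrasynaptic
  signal is defined by subtraction so that synaptic + extrasynaptic +
  background·(ROI pixels) equals the ROI total exactly (machine
  precision). Over-subtraction (negative extrasynaptic values) is
  flagged, never silently clamped. Sum-intensity measures are threshold-
  sensitive: a high (Otsu) threshold captures only punctum cores, while
  a near-background threshold recovers the full Gaussian integral; the
  analysis drivers report both.
* **Background.** When no value is supplied, background is estimated as
  the median intensity of ROI pixels outside all clusters — the
  estimator is a documented choice, since "background subtraction" alone
  does not pin down an estimator.
* **Outliers.** A single two-sided Grubbs removal at α = 0.05, critical
  value G = ((n−1)/√n)·√(t²/(n−2+t²)) with t the (1 − α/2n) quantile of
  t(n−2); never iterated, n ≥ 3 required. The cell (mean over its three
  10 μm dendrite ROIs) is the experimental unit.

## FRAP exchange kinetics

Recovery is reported on two scales: the percent-of-t0 scale
r(t) = (I(t)/I(0))·100 used for figures (it can exceed 100% and diverges
as I(0) → 0), and the pre-bleach fraction scale I(t)/pre used for
fitting. The kinetic model is a two-pool single-exponential exchange

    f(t) = d + m (1 − d)(1 − e^{−kt})

with bleach depth d ∈ [0, 1), mobile fraction m ∈ [0, 1], and exchange
rate k ≥ 0 per minute. This is a deliberate modeling choice: raw
recovery curves by themselves carry no kinetic model, and a single
exponential is the minimal description of exchange between a bleached
synaptic pool and an unbleached reservoir; no bleach-spot diffusion or
reaction–diffusion theory is attempted.

Fitting uses bounded least squares (`scipy.optimize.curve_fit`) with
data-derived initial values; a flat trace leaves k unidentified along
the k·m ≈ 0 ridge and is reported at the k = 0 boundary. `fit_exchange`
accepts a single trace, a pooled trace set, or a normalized curve (for
which only k and the recovery amplitude are identifiable).

**Sampling window.** The default time grid is every 2 min over 60 min
(31 points). The window matters: for k = 0.02/min the recovery half-time
is ~35 min, and a 30-min window leaves k and m strongly confounded
(per-trace median k biased upward by tens of percent at 5% noise); over
60 min the per-trace median recovers k within a few percent. Parameter
recovery claims are therefore tied to the 60-min default.

Group comparison is a classical two-factor (treatment × time)
fixed-effects ANOVA computed directly from the cell-mean decomposition
(exact for balanced designs; unbalanced cells use the unweighted-means
approximation with harmonic-mean cell size), with per-timepoint Tukey
HSD from the studentized-range distribution. Synapse-level repeated
measures are treated as independent replicates, matching the
conventional analysis of such experiments; no interpolation is performed
across missing timepoints — traces off the common grid are rejected.

## Intersubunit FRET

The emission model treats donor and acceptor as tags on paired subunits
within one receptor: observed donor = donor·(1−E); the FRET channel
carries E·coupling·min(donor, acceptor) plus an optional constant
bleed-through; the total-acceptor channel sees the acceptor under direct
excitation. Transfer requires both an excitable donor and an intact
acceptor, so bleaching the acceptor restores the donor (dequenching) and
quenching the donor (acidic extracellular saline) extinguishes the FRET
channel — the two specificity controls the pipeline analyzes. The
coupling constant (default 0.5) absorbs the uncalibrated absolute gain
of the FRET channel; only ratios are interpreted. No spectral unmixing
or bleed-through calibration matrices beyond the single constant, and no
Förster-radius distance estimation.

The four restriction criteria are applied strictly in order with a
per-criterion drop log. Boundary conventions: "at least" is inclusive
(criteria 1 and 3), the FRET:total ratio must be strictly < 1
(criterion 2), and the 300% sum cap is inclusive (criterion 4).
Criterion 4's reference average is computed over the synapses surviving
criteria 2–3 within the same cell; computing it over all measured
synapses is a defensible alternative, and the choice is localized in one
function. Criterion 2 uses sum intensities. The criteria are idempotent:
re-applying them to their own output changes nothing.

Acceptor-photobleach analysis averages ≥2 background-subtracted
pre-bleach frames against the post-bleach frames and reports donor
dequenching and Ê = 1 − donor_pre/donor_post, flagging bleaches that
fail to reduce the FRET channel by ≥50%. Defaults of 12 pre- and 24
post-bleach frames correspond to 5-s sampling over 1 min pre and 2 min
post. Normalization of cluster intensities to a control cohort is a
separate reporting step and never mutates stored records.

## Vesicle and lysosome assays

The surface/total ratio divides background-corrected ROI sums of the
surface-only image by the post-NH₄Cl (total) image; non-positive
denominators flag the ROI. The ratio is invariant to a common gain.

Spot detection targets bright circular objects of a nominal size
(default 0.75 μm) — the nominal size is treated as the object
**diameter**; the source protocols describe it variously as a
circumference and a circular area, and the parameter is configurable,
with the interpretation logged. The image is smoothed at a quarter of
the nominal size, the stringent intensity floor applied, and regions
kept when their equivalent diameter lies within 0.4–2× nominal and
their circularity — defined as the minor/major axis ratio, which is
stable for few-pixel regions where perimeter-based circularity is not —
is ≥ 0.8. New-vesicle counting matches post to pre spots greedily by
ascending distance within 0.5 μm (ties broken lexicographically by spot
id) and reports |post| − |matched|. No tracking over time and no
compartment-pH quantification.

## Interactome pipeline

The pipeline starts from exported weighted spectrum counts and exclusive
unique peptide counts; database searching and protein inference are
upstream and their thresholds are assumed already applied. Inclusion
requires (a) ≥2 exclusive unique peptides in some sample, (b) detection
in ≥3 specific-IP samples overall or ≥2 samples of one treatment group,
and (c) ≥3:1 enrichment over the IgG reference in ≥3 samples, where the
IgG reference is the per-protein mean over IgG samples (a per-sample
matched mode is available); a protein absent from every IgG sample is
trivially enriched. Removal reasons are logged per protein.

Ratios are mean(DZP)/mean(VEH) over per-animal counts with no
library-size normalization and no pseudocounts: a zero vehicle mean with
DZP signal is the sentinel class NF-V, the symmetric case NF-DZP, and
proteins absent from both groups are dropped. Significance is a
two-sided two-sample Student's t on the per-sample counts (raw p-values;
BH correction available by flag but off by default, matching the
convention of reporting raw p in association tables). Pathway input
maps NF-V → +1E+99, NF-DZP → −1E+99, ratios in (0, 1) → −1/ratio, and
leaves ratios ≥ 1 unchanged. Overrepresentation is a two-sided Fisher
exact test on the 2×2 detection table with Bonferroni correction over
the tested terms, run against a user-supplied annotation map — no
ontology database is queried.

The count generator is a gamma-Poisson (negative-binomial) mixture,
var = μ + φμ², with per-protein baseline proportions (log-normal,
σ = 1), per-sample expected totals (default 10⁴), planted multiplicative
DZP effects, and IgG samples at a fraction (default 0.05) of the
specific-IP mean; exclusive-unique-peptide counts are ≥1 wherever a
protein is detected and grow with the count. Defaults mirror a 3 + 3
animal design with one IgG control.

**Power limitation.** With n = 3 per group and dispersion φ = 0.3, the
two-sample t-test on raw counts has ~60% power at α = 0.1 for a 4-fold
effect (noncentral-t, df = 4) — a property of the design, not of the
implementation. Simulations at these settings recover planted 4-fold
proteins essentially completely by classification (ratio > 1), with a
median estimated ratio near 4, but only ~60% of them additionally reach
p < 0.1; the acceptance suite records this joint rate faithfully.

## Reproducibility

Every CLI stage writes a manifest (input hashes, parameters, seed,
package version); stochastic stages reproduce bit-exactly from the
recorded seed. The acceptance script regenerates all synthetic inputs
from `--seed` and recomputes every reported quantity at run time; its
problem sizes (60 traces/condition, 10-seed vesicle and count
simulations, 2×2 tables with margins ≤ 30 deduplicated by symmetry)
keep a full run under a minute on one CPU.
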