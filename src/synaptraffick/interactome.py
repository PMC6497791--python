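"""Co-IP spectral-count interactome pipeline.

Starting from exported weighted spectrum counts and exclusive unique
peptide counts (protein x sample), the pipeline applies the study's
inclusion criteria (peptide evidence, detection breadth, enrichment over
the IgG control), computes per-protein DZP/vehicle abundance ratios with
Student's t-tests, classifies proteins as increased / decreased /
unchanged with not-found (NF) sentinel handling, converts ratios to the
signed fold-change scale used for pathway analysis (-1/x for ratios in
(0, 1), +/-1E+99 for NF classes), and provides a generic Fisher-exact
overrepresentation test with Bonferroni correction over a user-supplied
annotation map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

NF_V_SENTINEL = 1e99       # not found in vehicle -> increased, +1E+99
NF_DZP_SENTINEL = -1e99    # not found in DZP -> decreased, -1E+99


@dataclass
class SpectralCountTable:
    """Protein x sample weighted spectrum counts with peptide evidence.

    ``counts`` and ``unique_peptides`` share index (protein) and columns
    (sample); ``sample_meta`` is indexed by sample with a ``treatment``
    column in {VEH, DZP, IgG}.
    """

    counts: pd.DataFrame
    unique_peptides: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.unique_peptides.index):
            raise ValueError("counts and unique_peptides protein index differ")
        if list(self.counts.columns) != list(self.unique_peptides.columns):
            raise ValueError("counts and unique_peptides samples differ")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        bad = set(self.sample_meta["treatment"]) - {"VEH", "DZP", "IgG"}
        if bad:
            raise ValueError(f"unknown treatments: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_of(self, treatment: str) -> list[str]:
        sel = self.sample_meta["treatment"] == treatment
        return [s for s in self.counts.columns if s in self.sample_meta.index[sel]]


def apply_inclusion_filter(
    table: SpectralCountTable,
    min_peptides: int = 2,
    min_samples_overall: int = 3,
    min_samples_in_group: int = 2,
    igg_enrichment: float = 3.0,
    igg_support: int = 3,
) -> tuple[SpectralCountTable, pd.DataFrame]:
    """Post-search inclusion filter over the count table.

    A protein is retained iff it (a) reaches ``min_peptides`` exclusive
    unique peptides in at least one sample, (b) is detected (count > 0)
    in >= ``min_samples_overall`` specific-IP samples overall or in
    >= ``min_samples_in_group`` samples of one treatment group, and
    (c) shows >= ``igg_enrichment``:1 enrichment over the IgG reference
    in >= ``igg_support`` specific-IP samples.  The IgG reference is the
    per-protein mean over IgG samples.  Returns the filtered table and a
    per-protein log of removal reasons.
    """
    igg_cols = table.samples_of("IgG")
    if not igg_cols:
        raise ValueError("inclusion filter requires IgG control samples")
    veh_cols = table.samples_of("VEH")
    dzp_cols = table.samples_of("DZP")
    spec_cols = veh_cols + dzp_cols

    counts = table.counts
    peptides = table.unique_peptides
    igg_ref = counts[igg_cols].mean(axis=1)

    pass_pep = peptides.max(axis=1) >= min_peptides
    det = counts[spec_cols] > 0
    pass_breadth = (
        (det.sum(axis=1) >= min_samples_overall)
        | (det[veh_cols].sum(axis=1) >= min_samples_in_group)
        | (det[dzp_cols].sum(axis=1) >= min_samples_in_group)
    )
    # enrichment: count >= ratio * IgG reference in >= igg_support samples;
    # a protein absent from every IgG sample is trivially enriched
    thresh = igg_enrichment * igg_ref
    enr = counts[spec_cols].gt(0, axis=0) & counts[spec_cols].ge(thresh, axis=0)
    pass_igg = (igg_ref == 0) | (enr.sum(axis=1) >= igg_support)

    reasons = pd.DataFrame({
        "pass_peptides": pass_pep,
        "pass_breadth": pass_breadth,
        "pass_igg_enrichment": pass_igg,
    })
    reasons["retained"] = reasons.all(axis=1)
    keep = reasons.index[reasons["retained"]]
    for prot, row in reasons[~reasons["retained"]].iterrows():
        why = [k for k in ("pass_peptides", "pass_breadth", "pass_igg_enrichment")
               if not row[k]]
        log.debug("excluded %s: failed %s", prot, ", ".join(why))
    filtered = SpectralCountTable(
        counts=counts.loc[keep].copy(),
        unique_peptides=peptides.loc[keep].copy(),
        sample_meta=table.sample_meta,
    )
    return filtered, reasons


@dataclass
class AssociationRecord:
    """Per-protein DZP/vehicle association summary."""

    protein: str
    ratio: float | None            # None for NF classes
    p_value: float | None
    klass: str                     # increased / decreased / NF_V / NF_DZP / unchanged
    dzp_mean: float | None = None
    veh_mean: float | None = None

    @property
    def pathway_fold_change(self) -> float:
        if self.klass == "NF_V":
            return NF_V_SENTINEL
        if self.klass == "NF_DZP":
            return NF_DZP_SENTINEL
        r = self.ratio
        if r is None:
            raise ValueError(f"{self.protein}: no ratio available")
        return -1.0 / r if 0 < r < 1 else r


def _classify_ratio(ratio: float | None, nf: str | None) -> str:
    if nf is not None:
        return nf
    if ratio > 1:
        return "increased"
    if ratio < 1:
        return "decreased"
    return "unchanged"


def compute_ratios(table: SpectralCountTable) -> list[AssociationRecord]:
    """DZP/V ratios, NF sentinel classes and two-sided Student's t-tests.

    ratio = mean(DZP counts)/mean(VEH counts) over per-animal weighted
    counts; a zero vehicle mean with DZP signal is NF_V, the symmetric
    case NF_DZP.  Proteins absent from both groups are dropped with a log
    entry.  Records are sorted by descending ratio with NF classes
    grouped after the numeric rows, mirroring the association tables.
    """
    veh_cols = table.samples_of("VEH")
    dzp_cols = table.samples_of("DZP")
    if len(veh_cols) < 2 or len(dzp_cols) < 2:
        raise ValueError("need >= 2 samples per treatment group")
    out: list[AssociationRecord] = []
    for prot, row in table.counts.iterrows():
        veh = row[veh_cols].to_numpy(dtype=float)
        dzp = row[dzp_cols].to_numpy(dtype=float)
        vm, dm = veh.mean(), dzp.mean()
        if vm == 0 and dm == 0:
            log.debug("dropped %s: absent from both treatment groups", prot)
            continue
        if vm > 0 and dm > 0:
            ratio = dm / vm
            nf = None
        elif vm == 0:
            ratio, nf = None, "NF_V"
        else:
            ratio, nf = None, "NF_DZP"
        if veh.std() == 0 and dzp.std() == 0:
            p = None if vm == dm else 0.0
        else:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(stats.ttest_ind(dzp, veh, equal_var=True).pvalue)
        out.append(AssociationRecord(
            protein=str(prot), ratio=ratio, p_value=p,
            klass=_classify_ratio(ratio, nf), dzp_mean=dm, veh_mean=vm))
    numeric = sorted((r for r in out if r.ratio is not None),
                     key=lambda r: (-r.ratio, r.protein))
    nf_v = sorted((r for r in out if r.klass == "NF_V"), key=lambda r: r.protein)
    nf_d = sorted((r for r in out if r.klass == "NF_DZP"), key=lambda r: r.protein)
    return numeric + nf_v + nf_d


@dataclass
class ClassificationCounts:
    increased: int
    increased_nf_v: int
    decreased: int
    decreased_nf_dzp: int
    unchanged: int


def classify_association(records: list[AssociationRecord]):
    """Partition records into increased / decreased / unchanged.

    Increased = ratio > 1 or NF_V (detected only under DZP); decreased =
    ratio < 1 or NF_DZP; a ratio of exactly 1 is unchanged.  Returns
    ``(increased, decreased, counts)``.
    """
    increased = [r for r in records if r.klass in ("increased", "NF_V")]
    decreased = [r for r in records if r.klass in ("decreased", "NF_DZP")]
    unchanged = [r for r in records if r.klass == "unchanged"]
    counts = ClassificationCounts(
        increased=len(increased),
        increased_nf_v=sum(r.klass == "NF_V" for r in increased),
        decreased=len(decreased),
        decreased_nf_dzp=sum(r.klass == "NF_DZP" for r in decreased),
        unchanged=len(unchanged),
    )
    return increased, decreased, counts


def to_pathway_input(records: list[AssociationRecord]) -> dict[str, float]:
    """Signed fold-change map for pathway analysis.

    NF_V -> +1E+99, NF_DZP -> -1E+99; ratios in (0, 1) become the negative
    inverse -1/x; ratios >= 1 pass through unchanged.
    """
    return {r.protein: r.pathway_fold_change for r in records}


def load_association_fixture() -> list[AssociationRecord]:
    """Packaged transcription of the in-paper DZP/V association tables."""
    with resources.files("synaptraffick.data").joinpath(
            "dzp_association_tables.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    records = []
    for _, row in df.iterrows():
        raw = row["ratio"]
        p = None if pd.isna(row["p_value"]) or row["p_value"] == "NA" \
            else float(row["p_value"])
        if raw in ("NF-V", "NF-DZP"):
            ratio, nf = None, raw.replace("-", "_")
        else:
            ratio, nf = float(raw), None
        records.append(AssociationRecord(
            protein=row["protein"], ratio=ratio, p_value=p,
            klass=_classify_ratio(ratio, nf)))
    return records


@dataclass
class EnrichmentResult:
    term: str
    fold_enrichment: float
    p_raw: float
    p_bonferroni: float
    hits_in_term: int
    term_size: int


def overrepresentation(
    hit_set: set[str],
    annotation: dict[str, set[str]],
    background: set[str],
) -> list[EnrichmentResult]:
    """Fisher-exact overrepresentation of annotation terms in a hit set.

    fold_enrichment = (hits-in-term/|hits|) / (background-in-term/|background|);
    p from the two-sided Fisher exact test on the 2x2 detection table,
    Bonferroni-corrected over the tested terms.
    """
    hit_set = set(hit_set)
    background = set(background)
    if not background or not hit_set:
        raise ValueError("hit set and background must be non-empty")
    if not hit_set <= background:
        raise ValueError("hit set must be a subset of the background")
    n_terms = len(annotation)
    out = []
    for term, members in annotation.items():
        members = set(members) & background
        k = len(hit_set & members)
        m = len(members)
        n_hit = len(hit_set)
        n_bg = len(background)
        table = [[k, n_hit - k],
                 [m - k, n_bg - n_hit - (m - k)]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        fe = (k / n_hit) / (m / n_bg) if m > 0 else np.nan
        out.append(EnrichmentResult(
            term=term, fold_enrichment=fe, p_raw=p,
            p_bonferroni=min(1.0, p * n_terms),
            hits_in_term=k, term_size=m))
    out.sort(key=lambda r: r.p_raw)
    return out


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Association records as a table mirroring the published columns."""
    return pd.DataFrame({
        "protein": [r.protein for r in records],
        "ratio_dzp_v": [r.ratio if r.ratio is not None
                        else r.klass.replace("_", "-") for r in records],
        "p_value": [r.p_value for r in records],
        "class": [r.klass for r in records],
        "pathway_fold_change": [r.pathway_fold_change for r in records],
    })
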