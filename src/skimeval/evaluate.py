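"""Accuracy and summary machinery for skim-versus-deep comparisons.

Every skim genotype matrix is scored against a deeply sequenced reference
under a matched-depth rule: if the skim set was depth-filtered at d, the
reference is depth-filtered at max(d, 2), so both sides face a comparable
evidence requirement and the reference never rests on a single read.
Cells fall into four categories — match, mismatch, missing-in-skim, and
not-evaluable (the reference itself lacks sufficient depth) — which
partition the matrix exactly. ``called_accuracy`` is the match fraction
among cells where both sides made a call.

Also here: the cumulative missing-data accuracy table (SNP counts and
accuracy when only sites under a per-site missing-fraction ceiling are
accepted), per-chromosome density summaries with 1-Mbp binning, the
de-novo versus list-based discovery audit, and per-individual genotype
yield statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_formats import (
    MISSING,
    AlleleDepthMatrix,
    GenotypeMatrix,
    SnpList,
)
from .filters import mask_by_depth

__all__ = [
    "MATCH",
    "MISMATCH",
    "MISSING_IN_SKIM",
    "NOT_EVALUABLE",
    "ConcordanceReport",
    "CumulativeAccuracyRow",
    "DensitySummary",
    "DeNovoComparison",
    "YieldSummary",
    "matched_reference_depth",
    "classify_cell",
    "classify_cells",
    "concordance",
    "cumulative_accuracy_table",
    "density_summary",
    "denovo_audit",
    "yield_summary",
    "exponential_fit_r2",
]

MATCH = 0
MISMATCH = 1
MISSING_IN_SKIM = 2
NOT_EVALUABLE = 3


def matched_reference_depth(skim_d: int) -> int:
    """Reference depth filter matched to a skim depth filter: max(d, 2)."""
    if skim_d < 0:
        raise ValueError("depth filter must be >= 0")
    return max(skim_d, 2)


def classify_cell(skim_gt: int, ref_gt: int) -> int:
    """Classify one (skim, reference) genotype pair.

    Reference MISSING -> NOT_EVALUABLE (regardless of the skim call);
    else skim MISSING -> MISSING_IN_SKIM; else MATCH/MISMATCH by equality.
    """
    if ref_gt == MISSING:
        return NOT_EVALUABLE
    if skim_gt == MISSING:
        return MISSING_IN_SKIM
    return MATCH if skim_gt == ref_gt else MISMATCH


def classify_cells(skim: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_cell`."""
    out = np.where(skim == ref, MATCH, MISMATCH)
    out[skim == MISSING] = MISSING_IN_SKIM
    out[ref == MISSING] = NOT_EVALUABLE
    return out


@dataclass
class ConcordanceReport:
    """Cell accounting of a skim matrix against a deep reference."""

    n_match: int
    n_mismatch: int
    n_missing_in_skim: int
    n_not_evaluable: int

    @property
    def total_cells(self) -> int:
        return (
            self.n_match
            + self.n_mismatch
            + self.n_missing_in_skim
            + self.n_not_evaluable
        )

    @property
    def overall_match_pct(self) -> float:
        return 100.0 * self.n_match / self.total_cells if self.total_cells else float("nan")

    @property
    def mismatch_pct(self) -> float:
        return 100.0 * self.n_mismatch / self.total_cells if self.total_cells else float("nan")

    @property
    def missing_pct(self) -> float:
        return (
            100.0 * self.n_missing_in_skim / self.total_cells
            if self.total_cells
            else float("nan")
        )

    @property
    def called_accuracy(self) -> float:
        """Match fraction among cells called on both sides; NaN if none."""
        called = self.n_match + self.n_mismatch
        return self.n_match / called if called else float("nan")

    def as_dict(self) -> dict:
        def pct(x: float) -> float | None:
            return None if np.isnan(x) else round(x, 1)

        return {
            "n_match": self.n_match,
            "n_mismatch": self.n_mismatch,
            "n_missing_in_skim": self.n_missing_in_skim,
            "n_not_evaluable": self.n_not_evaluable,
            "overall_match_pct": pct(self.overall_match_pct),
            "mismatch_pct": pct(self.mismatch_pct),
            "missing_pct": pct(self.missing_pct),
            "called_accuracy_pct": pct(100.0 * self.called_accuracy),
        }


def _check_aligned(skim: GenotypeMatrix, reference: GenotypeMatrix) -> None:
    if skim.sites != reference.sites:
        raise ValueError("skim and reference matrices index different sites")
    if [s.sample_id for s in skim.samples] != [s.sample_id for s in reference.samples]:
        raise ValueError("skim and reference matrices index different samples")


def concordance(
    skim: GenotypeMatrix,
    reference: GenotypeMatrix,
    skim_d: int = 0,
    ref_adm: AlleleDepthMatrix | None = None,
) -> ConcordanceReport:
    """Score a skim matrix against the deep reference.

    When ``ref_adm`` is given, the reference is first depth-masked at
    ``matched_reference_depth(skim_d)``; pass ``None`` if the reference
    is already masked (or is a noise-free truth matrix).
    """
    if ref_adm is not None:
        reference = mask_by_depth(
            reference, ref_adm, matched_reference_depth(skim_d)
        )
    _check_aligned(skim, reference)
    cls = classify_cells(skim.codes, reference.codes)
    counts = np.bincount(cls.reshape(-1), minlength=4)
    return ConcordanceReport(
        n_match=int(counts[MATCH]),
        n_mismatch=int(counts[MISMATCH]),
        n_missing_in_skim=int(counts[MISSING_IN_SKIM]),
        n_not_evaluable=int(counts[NOT_EVALUABLE]),
    )


@dataclass(frozen=True)
class CumulativeAccuracyRow:
    """One (missing-data ceiling) row of the cumulative accuracy table."""

    coverage: float
    min_depth: int
    missing_bin_upper: float
    snp_count: int
    called_accuracy_pct: float


def cumulative_accuracy_table(
    skim: GenotypeMatrix,
    reference: GenotypeMatrix,
    skim_d: int = 0,
    ref_adm: AlleleDepthMatrix | None = None,
    bins: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5),
    coverage: float = float("nan"),
) -> list[CumulativeAccuracyRow]:
    """SNP counts and called accuracy under per-site missing-data ceilings.

    For each ceiling b, only sites whose skim missing fraction is
    strictly below b are accepted (the table's ``<10% ... <50%``
    convention); counts are cumulative, i.e. non-decreasing in b.
    """
    if ref_adm is not None:
        reference = mask_by_depth(
            reference, ref_adm, matched_reference_depth(skim_d)
        )
    _check_aligned(skim, reference)
    miss_frac = skim.missing_fraction_per_site()
    rows = []
    for b in bins:
        mask = miss_frac < b
        rep = concordance(skim.subset_sites(mask), reference.subset_sites(mask))
        acc = rep.called_accuracy
        rows.append(
            CumulativeAccuracyRow(
                coverage=coverage,
                min_depth=skim_d,
                missing_bin_upper=b,
                snp_count=int(mask.sum()),
                called_accuracy_pct=round(100.0 * acc, 1) if not np.isnan(acc) else float("nan"),
            )
        )
    return rows


@dataclass
class DensitySummary:
    """Per-chromosome SNP density, normalised to the densest chromosome."""

    table: pd.DataFrame  # chromosome, snp_count, length_bp, density_per_mbp, relative_density
    bin_counts: dict[str, np.ndarray]  # chromosome -> counts in 1-Mbp bins


def density_summary(
    sites: SnpList,
    chrom_lengths: dict[str, int],
    length_normalised: bool = True,
    bin_size: int = 1_000_000,
) -> DensitySummary:
    """Summarise marker spread across chromosomes.

    Density is SNPs per Mbp (or raw counts with
    ``length_normalised=False``); the densest chromosome is assigned a
    relative density of 1. Bins are half-open ``[k*bin, (k+1)*bin)`` on
    the 0-based coordinate (position - 1).
    """
    known = set(chrom_lengths)
    for s in sites:
        if s.chromosome not in known:
            raise ValueError(f"no length for chromosome {s.chromosome!r}")
    chroms = sorted(chrom_lengths)
    counts = {c: 0 for c in chroms}
    positions: dict[str, list[int]] = {c: [] for c in chroms}
    for s in sites:
        counts[s.chromosome] += 1
        positions[s.chromosome].append(s.position)

    dens = []
    for c in chroms:
        if length_normalised:
            dens.append(counts[c] / (chrom_lengths[c] / 1e6))
        else:
            dens.append(float(counts[c]))
    max_d = max(dens) if dens else 0.0
    rel = [d / max_d if max_d > 0 else 0.0 for d in dens]

    table = pd.DataFrame(
        {
            "chromosome": chroms,
            "snp_count": [counts[c] for c in chroms],
            "length_bp": [chrom_lengths[c] for c in chroms],
            "density_per_mbp": dens if length_normalised else np.nan,
            "relative_density": rel,
        }
    )
    bin_counts = {}
    for c in chroms:
        n_bins = -(-chrom_lengths[c] // bin_size)
        pos = np.asarray(positions[c], dtype=int)
        idx = (pos - 1) // bin_size if len(pos) else np.empty(0, dtype=int)
        bin_counts[c] = np.bincount(idx, minlength=n_bins)
    return DensitySummary(table=table, bin_counts=bin_counts)


@dataclass
class DeNovoComparison:
    """De-novo discovery versus list-based genotyping accounting."""

    n_denovo: int
    n_listbased: int
    pct_list_reidentified: float
    fold_increase: float  # NaN when the list-based set is empty
    absolute_increase: int
    novel_audit: dict[str, float] = field(default_factory=dict)


def denovo_audit(
    denovo: SnpList,
    listbased: SnpList,
    denovo_gm: GenotypeMatrix | None = None,
    deep_gm: GenotypeMatrix | None = None,
) -> DeNovoComparison:
    """Compare a de-novo site set with the list-based set.

    ``fold_increase`` is n_denovo / n_listbased to 1 decimal (NaN for an
    empty list-based set); ``pct_list_reidentified`` is the share of
    list-based sites recovered de novo. When genotype matrices are given,
    the cells of novel sites (de novo minus list) are classified against
    the deep matrix into consistent / missing / incorrect fractions.
    """
    n_d, n_l = len(denovo), len(listbased)
    shared = len(listbased.intersection(denovo))
    fold = round(n_d / n_l, 1) if n_l else float("nan")
    pct = 100.0 * shared / n_l if n_l else float("nan")

    audit: dict[str, float] = {}
    novel = denovo.difference(listbased)
    if denovo_gm is not None and deep_gm is not None and len(novel):
        skim_sub = denovo_gm.restrict_to(novel)
        deep_sub = deep_gm.restrict_to(novel)
        _check_aligned(skim_sub, deep_sub)
        cls = classify_cells(skim_sub.codes, deep_sub.codes)
        evaluable = cls != NOT_EVALUABLE
        n_eval = int(evaluable.sum())
        if n_eval:
            audit = {
                "consistent": float((cls == MATCH).sum() / n_eval),
                "missing": float((cls == MISSING_IN_SKIM).sum() / n_eval),
                "incorrect": float((cls == MISMATCH).sum() / n_eval),
            }
    return DeNovoComparison(
        n_denovo=n_d,
        n_listbased=n_l,
        pct_list_reidentified=pct,
        fold_increase=fold,
        absolute_increase=n_d - n_l,
        novel_audit=audit,
    )


@dataclass
class YieldSummary:
    """Per-individual genotype yield (non-missing cells per sample)."""

    per_sample: np.ndarray
    average: float
    minimum: int
    maximum: int


def yield_summary(gm: GenotypeMatrix) -> YieldSummary:
    """Count genotyped (non-MISSING) sites per individual."""
    per_sample = (gm.codes != MISSING).sum(axis=0)
    if len(per_sample) == 0:
        return YieldSummary(per_sample, 0.0, 0, 0)
    return YieldSummary(
        per_sample=per_sample,
        average=float(per_sample.mean()),
        minimum=int(per_sample.min()),
        maximum=int(per_sample.max()),
    )


def exponential_fit_r2(coverages: np.ndarray, snp_counts: np.ndarray) -> float:
    """R-squared of a log-linear least-squares fit of counts vs coverage.

    Helper for judging whether marker counts grow exponentially with
    sequencing coverage; counts must be positive.
    """
    x = np.asarray(coverages, float)
    y = np.asarray(snp_counts, float)
    if (y <= 0).any():
        raise ValueError("snp counts must be positive for a log fit")
    ly = np.log(y)
    coef = np.polyfit(x, ly, 1)
    resid = ly - np.polyval(coef, x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
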