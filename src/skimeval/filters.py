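"""Site- and cell-level filtering of skim genotype matrices.

The stack, applied in a fixed order by :func:`apply_pipeline`:

1. triallelic handling — sites showing more than one alternate allele are
   dropped, masked to missing, or kept, per policy;
2. depth masking — cells supported by fewer than ``min_depth`` reads are
   set to MISSING;
3. missing-data filter — sites whose post-masking missing fraction
   exceeds ``max_missing`` are removed;
4. minor-allele-frequency filter — computed per subpopulation group from
   called genotypes; a site is retained if any group reaches the
   threshold (an ``all`` rule is available);
5. heterozygosity filter — sites whose heterozygote fraction among
   called genotypes exceeds ``max_het`` are removed.

All thresholds are inclusive on the retain side (missing <= max_missing,
MAF >= min_maf, het <= max_het). The order puts the depth mask before the
site filters so that missing/MAF/het judge the evidence that survives
depth filtering, which is what a depth-filtered skim set presents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .core_formats import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AlleleDepthMatrix,
    GenotypeMatrix,
)

__all__ = [
    "TriallelicPolicy",
    "MafRule",
    "FilterParams",
    "FilterReport",
    "mask_by_depth",
    "filter_missing",
    "filter_maf",
    "filter_het",
    "handle_triallelic",
    "apply_pipeline",
]


class TriallelicPolicy(str, Enum):
    DROP_SITE = "DROP_SITE"
    SET_MISSING = "SET_MISSING"
    KEEP = "KEEP"


class MafRule(str, Enum):
    ANY_GROUP = "ANY_GROUP"
    ALL_GROUPS = "ALL_GROUPS"


@dataclass
class FilterParams:
    """Thresholds of the filtering stack; ``None`` disables a rule.

    ``maf_groups`` maps group label -> sample index array; when empty, MAF
    is computed over all samples as one group.
    """

    min_depth: int = 0
    max_missing: float | None = 0.5
    min_maf: float | None = 0.05
    max_het: float | None = 0.1
    maf_groups: dict[str, np.ndarray] = field(default_factory=dict)
    maf_rule: MafRule = MafRule.ANY_GROUP
    triallelic_policy: TriallelicPolicy = TriallelicPolicy.DROP_SITE

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        for name in ("max_missing", "min_maf", "max_het"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def diversity_panel(cls, min_depth: int = 2, maf_groups: dict | None = None) -> "FilterParams":
        """Diverse-panel preset: missing 0.5, MAF 0.05 per group, het 0.1."""
        return cls(
            min_depth=min_depth,
            max_missing=0.5,
            min_maf=0.05,
            max_het=0.1,
            maf_groups=maf_groups or {},
            triallelic_policy=TriallelicPolicy.DROP_SITE,
        )

    @classmethod
    def four_parent(cls, min_depth: int = 4) -> "FilterParams":
        """Four-parent-cross preset: missing 0.5, MAF 0.01, no het filter."""
        return cls(
            min_depth=min_depth,
            max_missing=0.5,
            min_maf=0.01,
            max_het=None,
            triallelic_policy=TriallelicPolicy.DROP_SITE,
        )

    @classmethod
    def doubled_haploid(cls, min_depth: int = 1) -> "FilterParams":
        """DH preset: triallelic sites masked to missing, all sites kept."""
        return cls(
            min_depth=min_depth,
            max_missing=None,
            min_maf=None,
            max_het=None,
            triallelic_policy=TriallelicPolicy.SET_MISSING,
        )


@dataclass
class FilterReport:
    """Site and data-point accounting for one pipeline run."""

    sites_in: int
    sites_removed_per_rule: dict[str, int]
    sites_out: int
    n_samples: int
    residual_missing_fraction: float
    n_missing_genotypes: int

    @property
    def total_data_points(self) -> int:
        """SNPs x individuals: the data-point accounting unit."""
        return self.sites_out * self.n_samples

    def validate(self) -> None:
        if self.sites_in != self.sites_out + sum(self.sites_removed_per_rule.values()):
            raise AssertionError("site accounting does not balance")
        if not 0.0 <= self.residual_missing_fraction <= 1.0:
            raise AssertionError("residual missing fraction out of range")


def mask_by_depth(
    gm: GenotypeMatrix, adm: AlleleDepthMatrix, d: int
) -> GenotypeMatrix:
    """Set cells with total depth < d to MISSING; d = 0 is the identity."""
    if d < 0:
        raise ValueError("min depth must be >= 0")
    if gm.codes.shape != adm.ref_reads.shape:
        raise ValueError("genotype and depth matrices have different shapes")
    if d == 0:
        return gm.copy()
    out = gm.copy()
    out.codes[adm.total_depth < d] = MISSING
    return out


def filter_missing(gm: GenotypeMatrix, max_missing: float) -> GenotypeMatrix:
    """Remove sites whose missing fraction exceeds ``max_missing``.

    The fraction is computed over all samples; a site at exactly the
    threshold is retained.
    """
    keep = gm.missing_fraction_per_site() <= max_missing
    return gm.subset_sites(keep)


def _group_maf(codes: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Per-site minor allele frequency within one sample group.

    HOM counts two alleles, HET one of each; MISSING cells are excluded.
    Sites with no called genotype in the group get NaN.
    """
    sub = codes[:, cols]
    called = sub != MISSING
    n_alleles = 2 * called.sum(axis=1)
    alt = 2 * (sub == HOM_ALT).sum(axis=1) + (sub == HET).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return np.minimum(p, 1.0 - p)


def filter_maf(
    gm: GenotypeMatrix,
    min_maf: float,
    groups: dict[str, np.ndarray] | None = None,
    rule: MafRule = MafRule.ANY_GROUP,
) -> GenotypeMatrix:
    """Remove sites below the minor-allele-frequency threshold.

    MAF is computed separately within each sample group; under the
    default ANY_GROUP rule a site is retained iff at least one group
    reaches ``min_maf``. Sites with no called genotypes in any group are
    removed.
    """
    if not groups:
        groups = {"all": np.arange(gm.n_samples)}
    for label, cols in groups.items():
        if len(cols) == 0:
            raise ValueError(f"empty MAF group {label!r}")
    mafs = np.stack([_group_maf(gm.codes, np.asarray(cols)) for cols in groups.values()])
    passes = mafs >= min_maf  # NaN compares False
    keep = passes.any(axis=0) if rule is MafRule.ANY_GROUP else (
        passes | np.isnan(mafs)
    ).all(axis=0) & passes.any(axis=0)
    return gm.subset_sites(keep)


def filter_het(gm: GenotypeMatrix, max_het: float) -> GenotypeMatrix:
    """Remove sites whose heterozygote fraction among called genotypes
    exceeds ``max_het`` (boundary inclusive). All-missing sites pass."""
    called = (gm.codes != MISSING).sum(axis=1)
    het = (gm.codes == HET).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(called > 0, het / np.maximum(called, 1), 0.0)
    return gm.subset_sites(frac <= max_het)


def handle_triallelic(
    gm: GenotypeMatrix,
    adm: AlleleDepthMatrix | None,
    policy: TriallelicPolicy,
) -> GenotypeMatrix:
    """Apply the multi-allelic site policy.

    A site is triallelic when its record carries more than one alternate
    allele. DROP_SITE removes the site; SET_MISSING keeps the row but
    masks every cell; KEEP is the identity.
    """
    if not isinstance(policy, TriallelicPolicy):
        raise ValueError(f"unknown triallelic policy {policy!r}")
    tri = np.array([not s.is_biallelic for s in gm.sites], dtype=bool)
    if not tri.any() or policy is TriallelicPolicy.KEEP:
        return gm.copy()
    if policy is TriallelicPolicy.DROP_SITE:
        return gm.subset_sites(~tri)
    out = gm.copy()
    out.codes[tri, :] = MISSING
    return out


def apply_pipeline(
    gm: GenotypeMatrix,
    adm: AlleleDepthMatrix,
    params: FilterParams,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the full stack: triallelic -> depth -> missing -> MAF -> het.

    Returns the filtered matrix and a :class:`FilterReport` whose site
    accounting balances exactly (masking policies remove no sites and so
    contribute zero to the removal tally).
    """
    removed: dict[str, int] = {}
    sites_in = gm.n_sites

    step = handle_triallelic(gm, adm, params.triallelic_policy)
    removed["triallelic"] = sites_in - step.n_sites

    if params.min_depth > 0:
        keys = step.sites.key_set()
        mask = np.array([s.key in keys for s in adm.sites], dtype=bool)
        step = mask_by_depth(step, adm.subset_sites(mask), params.min_depth)

    if params.max_missing is not None:
        before = step.n_sites
        step = filter_missing(step, params.max_missing)
        removed["missing"] = before - step.n_sites
    else:
        removed["missing"] = 0

    if params.min_maf is not None:
        before = step.n_sites
        step = filter_maf(step, params.min_maf, params.maf_groups, params.maf_rule)
        removed["maf"] = before - step.n_sites
    else:
        removed["maf"] = 0

    if params.max_het is not None:
        before = step.n_sites
        step = filter_het(step, params.max_het)
        removed["het"] = before - step.n_sites
    else:
        removed["het"] = 0

    n_cells = step.n_sites * step.n_samples
    n_missing = int((step.codes == MISSING).sum())
    report = FilterReport(
        sites_in=sites_in,
        sites_removed_per_rule=removed,
        sites_out=step.n_sites,
        n_samples=step.n_samples,
        residual_missing_fraction=(n_missing / n_cells) if n_cells else 0.0,
        n_missing_genotypes=n_missing,
    )
    report.validate()
    return step, report
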