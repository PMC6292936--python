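"""Synthetic genotype and read-depth generator for skim-sequencing studies.

Emulates the statistical structure of low-coverage whole-genome
resequencing in three genetic backgrounds: a diverse panel (Hardy-Weinberg
genotypes with an inbreeding coefficient controlling heterozygote deficit),
four-parent crosses (offspring assembled from founder gametes, highly
heterozygous) and doubled haploids (fully homozygous truth, so any
heterozygous call downstream is an error signal).

Read generation is a two-stage sampling model: per-cell depth is Poisson
with a per-sample coverage multiplier (Gamma-distributed across samples to
hit a target coefficient of variation, emulating pooled sequencing), and
each read then reports one of the two alleles — a fair coin at heterozygous
cells, the true allele flipped with a small error probability at homozygous
cells. A configurable fraction of sites can be marked as collapsed-paralog
artifacts at which every sample's read pool looks heterozygous regardless
of its true genotype, mimicking consistent misalignment in a duplicated
genome. Sites are independent (no linkage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core_formats import (
    HET,
    HOM_ALT,
    HOM_REF,
    AlleleDepthMatrix,
    GenotypeMatrix,
    PopulationClass,
    SampleInfo,
    SnpList,
    SnpSite,
)

__all__ = [
    "CoverageProfile",
    "ErrorModel",
    "PopulationSpec",
    "uniform_maf",
    "simulate_truth",
    "sample_coverage_profile",
    "simulate_reads",
    "default_snp_list",
]


@dataclass
class CoverageProfile:
    """Per-sample sequencing coverage: a mean and a cross-sample spread.

    ``per_sample_multiplier`` scales each sample's mean coverage; the
    multipliers average ~1 so ``mean_coverage`` stays interpretable as the
    panel-wide mean.
    """

    mean_coverage: float
    cv: float
    per_sample_multiplier: np.ndarray

    def __post_init__(self) -> None:
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be >= 0")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        self.per_sample_multiplier = np.asarray(self.per_sample_multiplier, float)
        if (self.per_sample_multiplier < 0).any():
            raise ValueError("coverage multipliers must be positive")

    @property
    def sample_means(self) -> np.ndarray:
        """Per-sample mean coverage (fold)."""
        return self.mean_coverage * self.per_sample_multiplier


@dataclass(frozen=True)
class ErrorModel:
    """Read-level noise parameters.

    per_read_error
        Probability a read at a homozygous cell reports the paired
        alternate allele instead of the true one.
    artifact_site_fraction
        Fraction of sites that behave as collapsed paralogs: every
        sample's reads at such a site are drawn as if heterozygous.
    other_read_rate
        Probability a read reports a third allele (exercises triallelic
        handling); default 0.
    """

    per_read_error: float = 0.0
    artifact_site_fraction: float = 0.0
    other_read_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("per_read_error", "artifact_site_fraction", "other_read_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def uniform_maf(low: float = 0.05, high: float = 0.5) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Sampler drawing site allele frequencies uniformly from (low, high]."""

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(low, high, size=n)

    return sample


@dataclass
class PopulationSpec:
    """Recipe for a synthetic population's true genotypes."""

    population_class: PopulationClass
    n_samples: int
    n_sites: int
    maf_distribution: Callable[[np.random.Generator, int], np.ndarray] = field(
        default_factory=uniform_maf
    )
    inbreeding_coefficient: float = 0.0  # diverse panel only
    offspring_per_family: int = 19  # four-parent crosses only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_sites <= 0:
            raise ValueError("n_samples and n_sites must be positive")
        if not 0.0 <= self.inbreeding_coefficient <= 1.0:
            raise ValueError("inbreeding coefficient must be in [0, 1]")


def default_snp_list(n_sites: int, chrom: str = "chr1", spacing: int = 1000) -> SnpList:
    """Evenly spaced biallelic A/C sites on one chromosome."""
    return SnpList(
        [SnpSite(chrom, 1 + i * spacing, "A", ("C",)) for i in range(n_sites)],
        name="synthetic",
    )


def _make_samples(spec: PopulationSpec) -> list[SampleInfo]:
    return [
        SampleInfo(
            f"S{i:04d}",
            subpopulation="sim",
            population_class=spec.population_class,
            nominal_coverage=10.0,
        )
        for i in range(spec.n_samples)
    ]


def simulate_truth(spec: PopulationSpec, sites: SnpList | None = None) -> GenotypeMatrix:
    """Draw a true genotype matrix for the given population.

    Diverse panel: per site with alt frequency p and inbreeding F,
    genotypes are drawn with frequencies ``{(1-p)^2 + Fp(1-p),
    2p(1-p)(1-F), p^2 + Fp(1-p)}``. Doubled haploids: HOM_ALT with
    probability p, else HOM_REF — never heterozygous. Four-parent
    crosses: per family, eight founder haplotypes are drawn with allele
    frequency p and each offspring unites two gametes from two distinct
    founders. Truth contains no MISSING.
    """
    rng = np.random.default_rng(spec.seed)
    if sites is None:
        sites = default_snp_list(spec.n_sites)
    if len(sites) != spec.n_sites:
        raise ValueError("site list length does not match spec.n_sites")
    p = spec.maf_distribution(rng, spec.n_sites)
    if ((p <= 0) | (p > 0.5)).any():
        raise ValueError("maf_distribution must return frequencies in (0, 0.5]")
    n, m = spec.n_sites, spec.n_samples

    if spec.population_class is PopulationClass.DOUBLED_HAPLOID:
        codes = np.where(
            rng.random((n, m)) < p[:, None], HOM_ALT, HOM_REF
        ).astype(np.int8)
    elif spec.population_class is PopulationClass.DIVERSE_PANEL:
        F = spec.inbreeding_coefficient
        p2 = p[:, None]
        f_hom_ref = (1 - p2) ** 2 + F * p2 * (1 - p2)
        f_het = 2 * p2 * (1 - p2) * (1 - F)
        u = rng.random((n, m))
        codes = np.full((n, m), HOM_ALT, dtype=np.int8)
        codes[u < f_hom_ref + f_het] = HET
        codes[u < f_hom_ref] = HOM_REF
    elif spec.population_class is PopulationClass.FOUR_PARENT_CROSS:
        fam_size = max(1, spec.offspring_per_family)
        n_families = -(-m // fam_size)
        # 8 founder haplotypes per family, alleles iid Bernoulli(p) per site
        haplos = (
            rng.random((n, n_families, 8)) < p[:, None, None]
        ).astype(np.int8)
        codes = np.empty((n, m), dtype=np.int8)
        for j in range(m):
            fam = j // fam_size
            f1, f2 = rng.choice(4, size=2, replace=False)
            h1 = rng.integers(0, 2)
            h2 = rng.integers(0, 2)
            codes[:, j] = (
                haplos[:, fam, 2 * f1 + h1] + haplos[:, fam, 2 * f2 + h2]
            )
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown population class {spec.population_class}")

    return GenotypeMatrix(sites, _make_samples(spec), codes)


def sample_coverage_profile(
    mean: float, cv: float, n: int, seed: int | np.random.Generator = 0
) -> CoverageProfile:
    """Draw per-sample coverage multipliers hitting a target CV.

    Multipliers come from a Gamma distribution with shape ``1/cv**2`` and
    scale ``cv**2`` (mean 1, coefficient of variation ``cv``); ``cv=0``
    gives exactly 1 for every sample.
    """
    if mean < 0:
        raise ValueError("mean coverage must be >= 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if cv == 0:
        mult = np.ones(n)
    else:
        shape = 1.0 / cv**2
        mult = rng.gamma(shape, cv**2, size=n)
    return CoverageProfile(mean_coverage=mean, cv=cv, per_sample_multiplier=mult)


def simulate_reads(
    truth: GenotypeMatrix,
    profile: CoverageProfile,
    err: ErrorModel = ErrorModel(),
    seed: int | np.random.Generator = 0,
) -> AlleleDepthMatrix:
    """Sample an allele-depth matrix from true genotypes.

    Depth at (site, sample) is Poisson(mean_coverage x sample multiplier).
    At heterozygous cells (and at every cell of an artifact site) each
    read is the reference allele with probability 1/2; at homozygous cells
    each read reports the true allele, flipped to the paired alternate
    with probability ``per_read_error``. Artifact sites are chosen once
    per run and are the same for every sample. With ``other_read_rate``
    > 0 each read is first diverted to a third allele with that
    probability.
    """
    if len(profile.per_sample_multiplier) != truth.n_samples:
        raise ValueError("coverage profile does not match sample count")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n, m = truth.n_sites, truth.n_samples

    lam = profile.sample_means[None, :] * np.ones((n, 1))
    depth = rng.poisson(lam).astype(np.int32)

    artifact = np.zeros(n, dtype=bool)
    if err.artifact_site_fraction > 0:
        k = int(round(err.artifact_site_fraction * n))
        artifact[rng.choice(n, size=k, replace=False)] = True

    other = (
        rng.binomial(depth, err.other_read_rate).astype(np.int32)
        if err.other_read_rate > 0
        else np.zeros_like(depth)
    )
    informative = depth - other

    # probability a (non-other) read reports the alternate allele
    p_alt = np.zeros((n, m))
    codes = truth.codes
    p_alt[codes == HOM_REF] = err.per_read_error
    p_alt[codes == HOM_ALT] = 1.0 - err.per_read_error
    p_alt[codes == HET] = 0.5
    p_alt[artifact, :] = 0.5

    alt = rng.binomial(informative, p_alt).astype(np.int32)
    ref = (informative - alt).astype(np.int32)
    return AlleleDepthMatrix(
        truth.sites, list(truth.samples), ref, alt, other, has_allele_split=True
    )
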