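"""Closed-form design arithmetic for skim sequencing experiments.

Under Poisson-distributed per-site depth with mean coverage lambda, the
probability a cell survives a minimum-depth filter d is the Poisson upper
tail P(K >= d); an error-free heterozygous cell covered by k reads is
mis-called homozygous with probability 2^(1-k) (all reads drawing the
same allele). ``expected_called_accuracy`` combines these into the exact
expected concordance of the maximum-likelihood caller against truth, and
serves as the analytic oracle for the simulation pipeline.

The cost model is linear: a fixed per-sample library cost plus a per-Gb
sequencing cost, with coverage converted to data volume by the genome's
Gb-per-1x factor (default 1.0 Gb, appropriate for a genome assembling to
roughly one gigabase; e.g. pea would need ~4.3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .caller import CallerParams, call_genotypes_array
from .core_formats import HET, HOM_REF

__all__ = [
    "CostModel",
    "DesignPoint",
    "p_called",
    "p_het_undercall",
    "expected_called_accuracy",
    "cost_total",
    "affordable_samples",
]


@dataclass(frozen=True)
class CostModel:
    """Linear sequencing economics: library cost + per-Gb data cost."""

    lib_cost_per_sample: float = 12.0
    cost_per_gb: float = 30.0
    gb_per_1x: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lib_cost_per_sample", "cost_per_gb", "gb_per_1x"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def per_sample_cost(self, coverage: float) -> float:
        return self.lib_cost_per_sample + coverage * self.gb_per_1x * self.cost_per_gb


@dataclass(frozen=True)
class DesignPoint:
    """A candidate experiment: coverage, depth filter, samples, het rate."""

    coverage: float
    min_depth: int
    n_samples: int
    het_rate: float

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0.0 <= self.het_rate <= 1.0:
            raise ValueError("het_rate must be in [0, 1]")


def p_called(lam: float, d: int) -> float:
    """P(Poisson(lam) >= d): chance a cell survives a depth-d filter."""
    if lam <= 0:
        raise ValueError("coverage must be > 0")
    if d < 0:
        raise ValueError("depth must be >= 0")
    if d == 0:
        return 1.0
    return float(stats.poisson.sf(d - 1, lam))


def p_het_undercall(d_obs: int) -> float:
    """P(all reads at an error-free heterozygous cell carry one allele).

    With d_obs reads each drawing an allele fairly, both single-allele
    outcomes have probability 2^-d_obs, so the undercall probability is
    2^(1 - d_obs).
    """
    if d_obs < 1:
        raise ValueError("needs at least one observed read")
    return 2.0 ** (1 - d_obs)


def _accuracy_given_depth(k: int, het_rate: float, eps: float) -> float:
    """Expected caller correctness at fixed depth k >= 1."""
    params = CallerParams(per_read_error=eps)
    a = np.arange(k + 1)
    calls = call_genotypes_array((k - a)[None, :], a[None, :], params)[0]
    # truth HOM_REF: each read errs to alt with prob eps
    p_hom_correct = float(stats.binom.pmf(a, k, eps)[calls == HOM_REF].sum())
    # truth HET: each read is alt with prob 1/2
    p_het_correct = float(stats.binom.pmf(a, k, 0.5)[calls == HET].sum())
    return (1.0 - het_rate) * p_hom_correct + het_rate * p_het_correct


def expected_called_accuracy(
    lam: float, d: int, het_rate: float, eps: float = 0.0
) -> float:
    """Expected concordance with truth among depth-filtered, called cells.

    Mixture over Poisson depth k conditioned on k >= max(d, 1) (depth-0
    cells are missing, not wrong) of the ML caller's per-genotype
    correctness: heterozygotes are under-called with probability
    2^(1-k) at eps = 0, homozygotes mis-called via read errors at rate
    eps. Homozygous ref and alt are symmetric under the caller.
    """
    DesignPoint(coverage=lam, min_depth=d, n_samples=1, het_rate=het_rate)
    kmin = max(d, 1)
    kmax = int(stats.poisson.ppf(1 - 1e-13, lam)) + 10
    ks = np.arange(kmin, kmax + 1)
    weights = stats.poisson.pmf(ks, lam)
    total = weights.sum()
    if total <= 0:
        return 1.0  # no callable cells at this depth: vacuous accuracy
    weights = weights / total
    acc = np.array([_accuracy_given_depth(int(k), het_rate, eps) for k in ks])
    return float((weights * acc).sum())


def cost_total(n_samples: int, coverage: float, model: CostModel = CostModel()) -> float:
    """Total cost of sequencing ``n_samples`` to ``coverage`` fold."""
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    return n_samples * model.per_sample_cost(coverage)


def affordable_samples(
    budget: float, coverage: float, model: CostModel = CostModel()
) -> int:
    """Samples affordable at a budget, rounded to the nearest whole sample."""
    if budget < 0:
        raise ValueError("budget must be >= 0")
    per_sample = model.per_sample_cost(coverage)
    if per_sample <= 0:
        raise ValueError("per-sample cost must be > 0")
    return int(round(budget / per_sample))
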