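"""Maximum-likelihood genotype calling from per-allele read counts.

A two-allele stand-in for a pileup genotyper. Each read at a cell carries
the ref or the alt allele; under HOM_REF a read reports alt with
probability epsilon (the per-read error), under HOM_ALT it reports ref
with probability epsilon, and under HET each allele is equally likely.
The call is the maximum-likelihood genotype; zero depth is MISSING. This
makes the allele-sampling arithmetic exact: with epsilon = 0, a
heterozygous cell covered by k reads is mis-called homozygous with
probability 2^(1-k) — the insufficient-allele-sampling mechanism that
drives accuracy at low coverage.

Two modes mirror list-based versus de-novo genotyping: ``genotype_matrix``
calls every site of a supplied SNP list, while ``discover_sites`` emits
the sites whose read evidence alone supports a variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core_formats import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AlleleDepthMatrix,
    GenotypeMatrix,
    SnpList,
)

__all__ = ["CallerMode", "CallerParams", "call_genotype", "genotype_matrix", "discover_sites"]


class CallerMode(str, Enum):
    LIST_BASED = "LIST_BASED"
    DE_NOVO = "DE_NOVO"


@dataclass(frozen=True)
class CallerParams:
    """Parameters of the two-allele ML caller.

    per_read_error
        Probability a read at a homozygous cell reports the wrong allele
        of the pair; must be < 0.5 so homozygotes are identifiable.
    min_alt_reads_for_discovery
        De-novo mode only: a site is discovered when one sample shows at
        least this many alt reads (default 2, so a single read error
        cannot create a site) or at least two samples show any alt read.
    """

    per_read_error: float = 0.01
    mode: CallerMode = CallerMode.LIST_BASED
    min_alt_reads_for_discovery: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_read_error < 0.5:
            raise ValueError("per_read_error must be in [0, 0.5)")
        if self.min_alt_reads_for_discovery < 1:
            raise ValueError("min_alt_reads_for_discovery must be >= 1")


def _loglik(ref: np.ndarray, alt: np.ndarray, eps: float) -> tuple[np.ndarray, ...]:
    """Log-likelihoods (HOM_REF, HET, HOM_ALT) for count arrays."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_eps = np.log(eps) if eps > 0 else -np.inf
        log_1me = np.log1p(-eps)
        ll_rr = ref * log_1me + np.where(alt > 0, alt * log_eps, 0.0)
        ll_aa = alt * log_1me + np.where(ref > 0, ref * log_eps, 0.0)
        ll_het = (ref + alt) * np.log(0.5)
    return ll_rr, ll_het, ll_aa


def call_genotype(ref_reads: int, alt_reads: int, params: CallerParams) -> int:
    """ML genotype for a single cell; zero total depth gives MISSING.

    Exact likelihood ties are broken toward the homozygote of the
    majority allele, then HOM_REF.
    """
    return int(
        call_genotypes_array(
            np.array([[ref_reads]]), np.array([[alt_reads]]), params
        )[0, 0]
    )


def call_genotypes_array(
    ref: np.ndarray, alt: np.ndarray, params: CallerParams
) -> np.ndarray:
    """Vectorised :func:`call_genotype` over count arrays."""
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("read counts must be non-negative")
    ll_rr, ll_het, ll_aa = _loglik(ref, alt, params.per_read_error)
    best = np.maximum(np.maximum(ll_rr, ll_het), ll_aa)

    out = np.full(ref.shape, MISSING, dtype=np.int8)
    covered = (ref + alt) > 0
    # tie-break preference: homozygote of the majority allele, then
    # HOM_REF, then HOM_ALT, then HET — implemented by assigning in
    # reverse preference so the preferred call lands last
    out[covered & (ll_het == best)] = HET
    out[covered & (ll_aa == best)] = HOM_ALT
    out[covered & (ll_rr == best)] = HOM_REF
    maj_alt = covered & (alt > ref) & (ll_aa == best)
    out[maj_alt] = HOM_ALT
    return out


def genotype_matrix(
    adm: AlleleDepthMatrix, snp_list: SnpList, params: CallerParams
) -> GenotypeMatrix:
    """Call genotypes at every listed site present in the depth matrix.

    Sites absent from the list are absent from the output; order follows
    the depth matrix. Other-allele reads do not enter the two-allele
    likelihood (triallelic QC is a separate filtering concern).
    """
    adm.require_allele_split("genotype calling")
    matrix_chroms = {s.chromosome for s in adm.sites}
    list_chroms = {s.chromosome for s in snp_list}
    if len(snp_list) and len(adm.sites) and not (list_chroms & matrix_chroms):
        raise ValueError(
            "SNP list and depth matrix share no chromosome: "
            f"{sorted(list_chroms)} vs {sorted(matrix_chroms)}"
        )
    keys = snp_list.key_set()
    mask = np.array([s.key in keys for s in adm.sites], dtype=bool)
    sub = adm.subset_sites(mask)
    codes = call_genotypes_array(sub.ref_reads, sub.alt_reads, params)
    return GenotypeMatrix(sub.sites, list(sub.samples), codes)


def discover_sites(adm: AlleleDepthMatrix, params: CallerParams) -> SnpList:
    """De-novo site discovery from read evidence alone.

    A site is emitted iff at least one sample shows
    ``min_alt_reads_for_discovery`` alt reads, or at least two samples
    each show at least one alt read. Output is sorted (SnpList order).
    """
    adm.require_allele_split("variant discovery")
    strong = (adm.alt_reads >= params.min_alt_reads_for_discovery).any(axis=1)
    recurrent = (adm.alt_reads >= 1).sum(axis=1) >= 2
    keep = strong | recurrent
    return SnpList(
        [s for s, k in zip(adm.sites, keep) if k],
        name="de_novo",
    )
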