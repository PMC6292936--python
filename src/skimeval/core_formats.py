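"""Domain types and readers/writers for the formats the pipeline touches.

The central objects are :class:`GenotypeMatrix` (sites x samples grid of
genotype codes) and :class:`AlleleDepthMatrix` (per-cell read counts split
into ref / first-alt / other). Both are thin dataclasses over numpy arrays,
indexed by a :class:`SnpList` and an ordered list of :class:`SampleInfo`.

Conventions
-----------
* Coordinates are 1-based inclusive (VCF convention) everywhere.
* Genotype codes: ``HOM_REF=0, HET=1, HOM_ALT=2, MISSING=-1``.
* Phased and unphased genotypes are treated identically.
* ``MISSING`` reflects the GT field only; it is never inferred from depth
  at read time (depth masking is an explicit, separate step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "PopulationClass",
    "SnpSite",
    "SnpList",
    "SampleInfo",
    "GenotypeMatrix",
    "AlleleDepthMatrix",
    "FormatError",
    "read_vcf",
    "write_vcf",
    "read_snp_list",
    "write_snp_list",
    "read_sample_metadata",
    "write_sample_metadata",
]

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

_NUCLEOTIDES = frozenset("ACGT")


class FormatError(ValueError):
    """A file did not conform to the expected format."""


class PopulationClass(str, Enum):
    """Genetic background of a sample set.

    ``DIVERSE_PANEL``
        unrelated accessions; heterozygosity governed by allele frequency
        and an inbreeding coefficient.
    ``FOUR_PARENT_CROSS``
        offspring of inter-crossed founder quartets; highly heterozygous.
    ``DOUBLED_HAPLOID``
        fully homozygous lines; any heterozygous call is an error signal.
    """

    DIVERSE_PANEL = "DIVERSE_PANEL"
    FOUR_PARENT_CROSS = "FOUR_PARENT_CROSS"
    DOUBLED_HAPLOID = "DOUBLED_HAPLOID"


@dataclass(frozen=True)
class SnpSite:
    """A single SNP position with its reference and alternate alleles."""

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        alleles = (self.ref_allele, *self.alt_alleles)
        for a in alleles:
            if a not in _NUCLEOTIDES:
                raise ValueError(f"allele {a!r} is not a single nucleotide")
        if self.ref_allele in self.alt_alleles:
            raise ValueError("ref allele duplicated among alt alleles")
        if len(self.alt_alleles) < 1:
            raise ValueError("a SNP site needs at least one alt allele")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    @property
    def key(self) -> tuple[str, int]:
        return (self.chromosome, self.position)


class SnpList:
    """Ordered, deduplicated collection of :class:`SnpSite`.

    Sites are kept sorted by (chromosome, position); duplicate positions
    are rejected at construction. Supports set-style intersection and
    difference by (chromosome, position) key.
    """

    def __init__(self, sites: Iterable[SnpSite], name: str = ""):
        sites = sorted(sites, key=lambda s: s.key)
        seen: set[tuple[str, int]] = set()
        for s in sites:
            if s.key in seen:
                raise ValueError(f"duplicate site {s.key} in SNP list")
            seen.add(s.key)
        self._sites: list[SnpSite] = sites
        self.name = name

    def __len__(self) -> int:
        return len(self._sites)

    def __iter__(self) -> Iterator[SnpSite]:
        return iter(self._sites)

    def __getitem__(self, i: int) -> SnpSite:
        return self._sites[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpList):
            return NotImplemented
        return self._sites == other._sites

    def __repr__(self) -> str:
        label = f" {self.name!r}" if self.name else ""
        return f"<SnpList{label}: {len(self)} sites>"

    @property
    def keys(self) -> list[tuple[str, int]]:
        return [s.key for s in self._sites]

    def key_set(self) -> set[tuple[str, int]]:
        return {s.key for s in self._sites}

    def intersection(self, other: "SnpList") -> "SnpList":
        keys = other.key_set()
        return SnpList([s for s in self if s.key in keys], name=self.name)

    def difference(self, other: "SnpList") -> "SnpList":
        keys = other.key_set()
        return SnpList([s for s in self if s.key not in keys], name=self.name)

    def subset_mask(self, mask: np.ndarray, name: str | None = None) -> "SnpList":
        sites = [s for s, keep in zip(self._sites, mask) if keep]
        return SnpList(sites, name=self.name if name is None else name)


@dataclass(frozen=True)
class SampleInfo:
    """Identity and sequencing metadata of one sample."""

    sample_id: str
    subpopulation: str
    population_class: PopulationClass
    nominal_coverage: float

    def __post_init__(self) -> None:
        if self.nominal_coverage <= 0:
            raise ValueError("nominal_coverage must be > 0")


def _check_grid(n_sites: int, n_samples: int, *arrays: np.ndarray) -> None:
    for a in arrays:
        if a.shape != (n_sites, n_samples):
            raise ValueError(
                f"matrix shape {a.shape} does not match "
                f"({n_sites} sites, {n_samples} samples)"
            )


@dataclass
class GenotypeMatrix:
    """Sites x samples grid of genotype codes.

    ``codes[i, j]`` is the genotype of sample ``j`` at site ``i``, one of
    ``HOM_REF``, ``HET``, ``HOM_ALT`` or ``MISSING``.
    """

    sites: SnpList
    samples: list[SampleInfo]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        _check_grid(len(self.sites), len(self.samples), self.codes)
        valid = np.isin(self.codes, (HOM_REF, HET, HOM_ALT, MISSING))
        if not valid.all():
            bad = np.unique(self.codes[~valid])
            raise ValueError(f"invalid genotype codes: {bad.tolist()}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sites, list(self.samples), self.codes.copy())

    def missing_fraction_per_site(self) -> np.ndarray:
        """Fraction of MISSING cells per site, over all samples."""
        if self.n_samples == 0:
            return np.zeros(self.n_sites)
        return (self.codes == MISSING).mean(axis=1)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            self.sites.subset_mask(mask), list(self.samples), self.codes[mask]
        )

    def restrict_to(self, sites: SnpList) -> "GenotypeMatrix":
        keys = sites.key_set()
        mask = np.array([s.key in keys for s in self.sites], dtype=bool)
        return self.subset_sites(mask)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sites == other.sites
            and [s.sample_id for s in self.samples]
            == [s.sample_id for s in other.samples]
            and np.array_equal(self.codes, other.codes)
        )


@dataclass
class AlleleDepthMatrix:
    """Per-cell read counts: reference, first alternate, and any other allele.

    ``has_allele_split`` is False when the source carried only total depth
    (no AD field); total depth is then stored in ``ref_reads`` and
    allele-aware operations must refuse to guess the split.
    """

    sites: SnpList
    samples: list[SampleInfo]
    ref_reads: np.ndarray
    alt_reads: np.ndarray
    other_reads: np.ndarray
    has_allele_split: bool = True

    def __post_init__(self) -> None:
        self.ref_reads = np.asarray(self.ref_reads, dtype=np.int32)
        self.alt_reads = np.asarray(self.alt_reads, dtype=np.int32)
        self.other_reads = np.asarray(self.other_reads, dtype=np.int32)
        _check_grid(
            len(self.sites),
            len(self.samples),
            self.ref_reads,
            self.alt_reads,
            self.other_reads,
        )
        for a in (self.ref_reads, self.alt_reads, self.other_reads):
            if (a < 0).any():
                raise ValueError("read counts must be non-negative")

    @property
    def total_depth(self) -> np.ndarray:
        return self.ref_reads + self.alt_reads + self.other_reads

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def require_allele_split(self, operation: str) -> None:
        if not self.has_allele_split:
            raise ValueError(
                f"{operation} needs per-allele depths (AD), but this matrix "
                "carries total depth only"
            )

    def copy(self) -> "AlleleDepthMatrix":
        return AlleleDepthMatrix(
            self.sites,
            list(self.samples),
            self.ref_reads.copy(),
            self.alt_reads.copy(),
            self.other_reads.copy(),
            self.has_allele_split,
        )

    def subset_sites(self, mask: np.ndarray) -> "AlleleDepthMatrix":
        mask = np.asarray(mask, dtype=bool)
        return AlleleDepthMatrix(
            self.sites.subset_mask(mask),
            list(self.samples),
            self.ref_reads[mask],
            self.alt_reads[mask],
            self.other_reads[mask],
            self.has_allele_split,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleDepthMatrix):
            return NotImplemented
        return (
            self.sites == other.sites
            and [s.sample_id for s in self.samples]
            == [s.sample_id for s in other.samples]
            and np.array_equal(self.ref_reads, other.ref_reads)
            and np.array_equal(self.alt_reads, other.alt_reads)
            and np.array_equal(self.other_reads, other.other_reads)
            and self.has_allele_split == other.has_allele_split
        )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_vcf(
    path: str, sample_meta: Sequence[SampleInfo]
) -> tuple[GenotypeMatrix, AlleleDepthMatrix]:
    """Read a VCF into paired genotype and allele-depth matrices.

    Sample (column) order is taken from ``sample_meta``, not the VCF
    header; the two must contain exactly the same sample ids. Records
    with more than one alternate allele are retained with all alternates
    so that downstream triallelic handling can see them.

    Parameters
    ----------
    path : str
        Path to a VCF (v4.x) with FORMAT fields GT and DP; AD is optional.
    sample_meta : sequence of SampleInfo
        Metadata rows defining the sample order of the matrices.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad input
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc

    file_samples = list(vcf.samples)
    meta_ids = [s.sample_id for s in sample_meta]
    extra = sorted(set(file_samples) - set(meta_ids))
    if extra:
        raise FormatError(f"VCF samples absent from metadata: {', '.join(extra)}")
    absent = sorted(set(meta_ids) - set(file_samples))
    if absent:
        raise FormatError(f"metadata samples absent from VCF: {', '.join(absent)}")
    order = np.array([file_samples.index(sid) for sid in meta_ids])

    sites: list[SnpSite] = []
    codes_rows: list[np.ndarray] = []
    ref_rows: list[np.ndarray] = []
    alt_rows: list[np.ndarray] = []
    other_rows: list[np.ndarray] = []
    has_ad = True

    for line_no, var in enumerate(vcf, start=1):
        try:
            site = SnpSite(var.CHROM, var.POS, var.REF, tuple(var.ALT))
        except ValueError as exc:
            raise FormatError(f"record {line_no} ({var.CHROM}:{var.POS}): {exc}") from exc
        sites.append(site)

        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = var.gt_types[order].astype(np.int8)
        gt[gt == 3] = MISSING
        codes_rows.append(gt)

        ad = var.format("AD")
        if ad is None:
            has_ad = False
            dp = var.format("DP")
            depth = (
                np.zeros(len(order), dtype=np.int32)
                if dp is None
                else np.clip(dp.reshape(-1)[order], 0, None).astype(np.int32)
            )
            ref_rows.append(depth)
            alt_rows.append(np.zeros_like(depth))
            other_rows.append(np.zeros_like(depth))
        else:
            ad = np.clip(ad[order], 0, None).astype(np.int32)
            ref_rows.append(ad[:, 0])
            alt_rows.append(ad[:, 1] if ad.shape[1] > 1 else np.zeros_like(ad[:, 0]))
            other_rows.append(
                ad[:, 2:].sum(axis=1) if ad.shape[1] > 2 else np.zeros_like(ad[:, 0])
            )

    n = len(order)
    snp_list = SnpList(sites, name=path)
    shape = (len(sites), n)
    gm = GenotypeMatrix(
        snp_list,
        list(sample_meta),
        np.vstack(codes_rows) if sites else np.empty(shape, dtype=np.int8),
    )
    adm = AlleleDepthMatrix(
        snp_list,
        list(sample_meta),
        np.vstack(ref_rows) if sites else np.empty(shape, dtype=np.int32),
        np.vstack(alt_rows) if sites else np.empty(shape, dtype=np.int32),
        np.vstack(other_rows) if sites else np.empty(shape, dtype=np.int32),
        has_allele_split=has_ad,
    )
    return gm, adm


_GT_STRINGS = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1)}


def write_vcf(gm: GenotypeMatrix, adm: AlleleDepthMatrix, path: str) -> str:
    """Write paired matrices to a VCF readable by :func:`read_vcf`.

    AD is emitted as three numbers per cell (ref, first alt, other) when
    the depth matrix carries an allele split; otherwise only DP is written.
    Round-trips through :func:`read_vcf` on codes, DP and AD.
    """
    import pysam

    if gm.n_sites != adm.n_sites or gm.n_samples != adm.n_samples:
        raise ValueError("genotype and depth matrices have different shapes")
    if gm.sites != adm.sites:
        raise ValueError("genotype and depth matrices index different sites")

    header = pysam.VariantHeader()
    header.add_meta("source", "skimeval")
    for chrom in dict.fromkeys(s.chromosome for s in gm.sites):
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    if adm.has_allele_split:
        header.formats.add(
            "AD", ".", "Integer", "Read depth per allele: ref, first alt, other"
        )
    for s in gm.samples:
        header.add_sample(s.sample_id)

    total = adm.total_depth
    with pysam.VariantFile(path, "w", header=header) as out:
        for i, site in enumerate(gm.sites):
            rec = out.new_record(
                contig=site.chromosome,
                start=site.position - 1,
                alleles=(site.ref_allele, *site.alt_alleles),
            )
            for j, s in enumerate(gm.samples):
                code = int(gm.codes[i, j])
                rec.samples[s.sample_id]["GT"] = _GT_STRINGS.get(code, (None, None))
                rec.samples[s.sample_id]["DP"] = int(total[i, j])
                if adm.has_allele_split:
                    rec.samples[s.sample_id]["AD"] = (
                        int(adm.ref_reads[i, j]),
                        int(adm.alt_reads[i, j]),
                        int(adm.other_reads[i, j]),
                    )
            out.write(rec)
    return path


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------

_SNP_LIST_COLUMNS = ["chrom", "pos", "ref", "alt"]


def read_snp_list(path: str, name: str | None = None) -> SnpList:
    """Read a TSV SNP list (``chrom  pos  ref  alt``, with header).

    Multiple alternate alleles are comma-separated in the ``alt`` column.
    Duplicate (chrom, pos) rows are collapsed to the first occurrence with
    a warning. Output is sorted by chromosome then position.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing_cols = [c for c in _SNP_LIST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"SNP list missing columns: {missing_cols}")
    try:
        positions = df["pos"].astype(int)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-integer position in SNP list: {exc}") from exc
    if (positions < 1).any():
        bad = df.loc[positions < 1]
        raise FormatError(f"positions < 1 in SNP list at rows {bad.index.tolist()}")

    dup = df.duplicated(subset=["chrom", "pos"], keep="first")
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate (chrom, pos) rows collapsed to first "
            f"occurrence in {path}",
            stacklevel=2,
        )
        df = df.loc[~dup]
        positions = positions.loc[~dup]

    sites = [
        SnpSite(str(c), int(p), r, tuple(a.split(",")))
        for c, p, r, a in zip(df["chrom"], positions, df["ref"], df["alt"])
    ]
    return SnpList(sites, name=path if name is None else name)


def write_snp_list(snps: SnpList, path: str) -> str:
    df = pd.DataFrame(
        {
            "chrom": [s.chromosome for s in snps],
            "pos": [s.position for s in snps],
            "ref": [s.ref_allele for s in snps],
            "alt": [",".join(s.alt_alleles) for s in snps],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


_META_COLUMNS = ["sample_id", "subpopulation", "population_class", "nominal_coverage"]


def read_sample_metadata(path: str) -> list[SampleInfo]:
    """Read a sample metadata TSV (see :data:`_META_COLUMNS` for layout)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subpopulation": str})
    missing_cols = [c for c in _META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"sample metadata missing columns: {missing_cols}")
    out = []
    for row in df.itertuples(index=False):
        try:
            pc = PopulationClass(row.population_class)
        except ValueError as exc:
            raise FormatError(
                f"unknown population class {row.population_class!r} "
                f"for sample {row.sample_id}"
            ) from exc
        out.append(
            SampleInfo(row.sample_id, row.subpopulation, pc, float(row.nominal_coverage))
        )
    return out


def write_sample_metadata(samples: Sequence[SampleInfo], path: str) -> str:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "subpopulation": [s.subpopulation for s in samples],
            "population_class": [s.population_class.value for s in samples],
            "nominal_coverage": [s.nominal_coverage for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path
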