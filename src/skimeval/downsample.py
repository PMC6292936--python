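"""In-silico skim-set construction: FASTQ read subsetting and depth thinning.

A deep sample is turned into a skim sample by keeping each read (or read
pair) independently with probability ``target / nominal`` coverage. At the
matrix level the same operation is binomial thinning of per-allele read
counts, which by the Poisson thinning theorem maps Poisson(lambda) depths
to Poisson(fraction * lambda) depths — the matrix analogue of subsetting
reads before alignment.

Selection is per-read Bernoulli rather than exact-count sampling: output
counts are Binomial(N, fraction), preserving the coverage variability a
pooled sequencing run would show, and the implementation streams in O(1)
memory. Each file's random stream is derived from the master seed plus a
stable hash of the file name, so adding samples to a batch never perturbs
existing outputs.
"""

from __future__ import annotations

import gzip
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_formats import AlleleDepthMatrix, FormatError

__all__ = ["SkimFraction", "subsample_fastq", "thin_depths"]


@dataclass(frozen=True)
class SkimFraction:
    """Coverage down-sampling factor: keep ``target/nominal`` of the reads."""

    target_coverage: float
    nominal_coverage: float

    def __post_init__(self) -> None:
        if self.nominal_coverage <= 0:
            raise ValueError("nominal coverage must be > 0")
        if not 0 < self.fraction <= 1:
            raise ValueError(
                f"fraction {self.fraction} outside (0, 1]; target coverage must "
                "be positive and at most the nominal coverage"
            )

    @property
    def fraction(self) -> float:
        return self.target_coverage / self.nominal_coverage


def _stream_seed(master_seed: int, name: str) -> np.random.Generator:
    # stable per-file stream: master seed + CRC32 of the file's base name
    return np.random.default_rng((int(master_seed), zlib.crc32(name.encode())))


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _fastq_records(handle, path):
    """Yield (header, seq, plus, qual) tuples, validating record shape."""
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline()
        plus = handle.readline()
        qual = handle.readline()
        if not qual:
            raise FormatError(f"truncated FASTQ record at end of {path}")
        if not header.startswith("@") or not plus.startswith("+"):
            raise FormatError(f"malformed FASTQ record {header.strip()!r} in {path}")
        if len(seq.strip()) != len(qual.strip()):
            raise FormatError(
                f"sequence/quality length mismatch for {header.strip()!r} in {path}"
            )
        yield header, seq, plus, qual


def subsample_fastq(
    reads_in: str | Path | tuple[str | Path, str | Path],
    frac: SkimFraction,
    seed: int = 0,
    out: str | Path | tuple[str | Path, str | Path] | None = None,
) -> tuple[Path, ...]:
    """Keep each read (pair) independently with probability ``frac.fraction``.

    ``reads_in`` is a single FASTQ path or an (R1, R2) pair; pairs are kept
    or dropped together, so the two outputs always carry identical read-id
    sequences. Files ending in ``.gz`` are (de)compressed transparently.
    Output paths default to ``<stem>.skim<target>x<suffix>``.

    Returns the tuple of output paths.
    """
    paired = isinstance(reads_in, (tuple, list))
    in_paths = tuple(Path(p) for p in (reads_in if paired else (reads_in,)))

    if out is None:
        tag = f".skim{frac.target_coverage:g}x"
        out_paths = tuple(
            p.with_name(p.name.replace(".fastq", f"{tag}.fastq", 1))
            if ".fastq" in p.name
            else p.with_name(p.name + tag)
            for p in in_paths
        )
    else:
        out_paths = tuple(Path(p) for p in (out if paired else (out,)))

    rng = _stream_seed(seed, in_paths[0].name)
    p = frac.fraction

    handles_in = [_open_text(p) for p in in_paths]
    handles_out = [_open_text(p, "wt") for p in out_paths]
    try:
        iters = [_fastq_records(h, p) for h, p in zip(handles_in, in_paths)]
        while True:
            records = []
            ended = 0
            for it in iters:
                rec = next(it, None)
                if rec is None:
                    ended += 1
                records.append(rec)
            if ended == len(iters):
                break
            if ended:
                raise FormatError("paired FASTQ files have different record counts")
            keep = p >= 1.0 or rng.random() < p
            if keep:
                for rec, h in zip(records, handles_out):
                    h.writelines(rec)
    finally:
        for h in (*handles_in, *handles_out):
            h.close()
    return out_paths


def thin_depths(
    adm: AlleleDepthMatrix, frac: SkimFraction, seed: int = 0
) -> AlleleDepthMatrix:
    """Binomially thin every read count by ``frac.fraction``.

    Each of the ref / alt / other counts is replaced by an independent
    Binomial(count, fraction) draw. Thinning a Poisson depth field by p
    yields a Poisson field with mean scaled by p, so this is the matrix
    analogue of read subsetting; ``fraction = 1`` is the identity.
    """
    p = frac.fraction
    if p == 1.0:
        return adm.copy()
    rng = np.random.default_rng(seed)
    return AlleleDepthMatrix(
        adm.sites,
        list(adm.samples),
        rng.binomial(adm.ref_reads, p).astype(np.int32),
        rng.binomial(adm.alt_reads, p).astype(np.int32),
        rng.binomial(adm.other_reads, p).astype(np.int32),
        adm.has_allele_split,
    )
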