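import numpy as np
import pytest

from skimeval.core_formats import (
    AlleleDepthMatrix,
    GenotypeMatrix,
    PopulationClass,
    SampleInfo,
    SnpList,
    SnpSite,
)


def make_sites(n, chrom="chr1", spacing=100):
    return SnpList(
        [SnpSite(chrom, 1 + i * spacing, "A", ("C",)) for i in range(n)],
        name="test",
    )


def make_samples(n, population_class=PopulationClass.DIVERSE_PANEL, subpop="pop"):
    return [
        SampleInfo(f"S{i:03d}", subpop, population_class, 10.0) for i in range(n)
    ]


def make_gm(codes, sites=None, samples=None):
    codes = np.asarray(codes, dtype=np.int8)
    if sites is None:
        sites = make_sites(codes.shape[0])
    if samples is None:
        samples = make_samples(codes.shape[1])
    return GenotypeMatrix(sites, samples, codes)


def make_adm(ref, alt=None, other=None, sites=None, samples=None):
    ref = np.asarray(ref, dtype=np.int32)
    alt = np.zeros_like(ref) if alt is None else np.asarray(alt, dtype=np.int32)
    other = np.zeros_like(ref) if other is None else np.asarray(other, dtype=np.int32)
    if sites is None:
        sites = make_sites(ref.shape[0])
    if samples is None:
        samples = make_samples(ref.shape[1])
    return AlleleDepthMatrix(sites, samples, ref, alt, other)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
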