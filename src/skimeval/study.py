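"""End-to-end study orchestration: the coverage x depth-filter grid.

Wires simulate -> downsample -> caller -> filters -> evaluate into the
two study workflows: an in-silico evaluation where deep synthetic data is
thinned to a grid of skim coverages and scored against the deep calls,
and an experimental-style application of a population-class preset
(diversity panel, four-parent cross, doubled haploid) to one data set.
Every bundle embeds its seed and a config hash so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .caller import CallerParams, genotype_matrix
from .core_formats import MISSING, AlleleDepthMatrix, GenotypeMatrix, PopulationClass
from .downsample import SkimFraction, thin_depths
from .evaluate import concordance, cumulative_accuracy_table, matched_reference_depth, yield_summary
from .filters import FilterParams, apply_pipeline, mask_by_depth
from .simulate import (
    CoverageProfile,
    ErrorModel,
    PopulationSpec,
    sample_coverage_profile,
    simulate_reads,
    simulate_truth,
)

__all__ = ["StudyConfig", "run_in_silico_study", "run_experimental"]

# the study's coverage x depth grid
DEFAULT_COVERAGES = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_DEPTHS = (2, 3, 4, 5)


@dataclass
class StudyConfig:
    """Parameters of one simulated study run."""

    population_class: PopulationClass = PopulationClass.DIVERSE_PANEL
    n_samples: int = 50
    n_sites: int = 2000
    nominal_coverage: float = 10.0
    coverage_cv: float = 0.27
    per_read_error: float = 0.002
    artifact_site_fraction: float = 0.0
    # canola accessions are predominantly inbred (DH-derived breeding
    # lines), so true heterozygosity sits well below the 0.1 QC cap
    inbreeding_coefficient: float = 0.9
    coverages: tuple[float, ...] = DEFAULT_COVERAGES
    depths: tuple[int, ...] = DEFAULT_DEPTHS
    caller_error: float = 0.01
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {
            "tool": f"skimeval {__version__}",
            "seed": self.seed,
            "config_hash": self.config_hash(),
        }


def _simulate_deep(config: StudyConfig):
    spec = PopulationSpec(
        population_class=config.population_class,
        n_samples=config.n_samples,
        n_sites=config.n_sites,
        inbreeding_coefficient=config.inbreeding_coefficient,
        seed=config.seed,
    )
    truth = simulate_truth(spec)
    profile = sample_coverage_profile(
        config.nominal_coverage, config.coverage_cv, config.n_samples, seed=config.seed + 1
    )
    err = ErrorModel(
        per_read_error=config.per_read_error,
        artifact_site_fraction=config.artifact_site_fraction,
    )
    deep_adm = simulate_reads(truth, profile, err, seed=config.seed + 2)
    return truth, profile, err, deep_adm


def _filter_preset(config: StudyConfig, d: int) -> FilterParams:
    if config.population_class is PopulationClass.DIVERSE_PANEL:
        return FilterParams.diversity_panel(min_depth=d)
    if config.population_class is PopulationClass.FOUR_PARENT_CROSS:
        return FilterParams.four_parent(min_depth=d)
    return FilterParams.doubled_haploid(min_depth=d)


def run_in_silico_study(config: StudyConfig) -> dict:
    """Thin deep synthetic data over the coverage x depth grid and score it.

    For each (coverage, depth) pair: binomially thin the deep read
    matrix, genotype the listed sites, apply the population preset's
    filter stack at that depth, and compare against the deep calls masked
    at the matched reference depth. Returns a JSON-serialisable bundle
    with per-pair SNP counts, concordance decompositions and cumulative
    missing-data accuracy rows.
    """
    truth, profile, err, deep_adm = _simulate_deep(config)
    params = CallerParams(per_read_error=config.caller_error)
    deep_gm = genotype_matrix(deep_adm, truth.sites, params)

    reports = []
    for cov in config.coverages:
        frac = SkimFraction(cov, config.nominal_coverage)
        skim_adm = thin_depths(
            deep_adm, frac, seed=config.seed + 1000 + int(cov * 100)
        )
        skim_calls = genotype_matrix(skim_adm, truth.sites, params)
        for d in config.depths:
            fp = _filter_preset(config, d)
            filtered, freport = apply_pipeline(skim_calls, skim_adm, fp)
            keys = filtered.sites.key_set()
            site_mask = np.array([s.key in keys for s in truth.sites], dtype=bool)
            ref_gm = deep_gm.subset_sites(site_mask)
            ref_adm = deep_adm.subset_sites(site_mask)
            rep = concordance(filtered, ref_gm, skim_d=d, ref_adm=ref_adm)
            cum = cumulative_accuracy_table(
                filtered, ref_gm, skim_d=d, ref_adm=ref_adm, coverage=cov
            )
            reports.append(
                {
                    "coverage": cov,
                    "min_depth": d,
                    "snp_count": filtered.n_sites,
                    "sites_removed": freport.sites_removed_per_rule,
                    "concordance": rep.as_dict(),
                    "cumulative": [
                        {
                            "missing_bin_upper": r.missing_bin_upper,
                            "snp_count": r.snp_count,
                            "called_accuracy_pct": None
                            if np.isnan(r.called_accuracy_pct)
                            else r.called_accuracy_pct,
                        }
                        for r in cum
                    ],
                }
            )
    return {"provenance": config.provenance(), "reports": reports}


def run_experimental(
    config: StudyConfig,
    gm: GenotypeMatrix | None = None,
    adm: AlleleDepthMatrix | None = None,
) -> dict:
    """Apply the population-class preset to one data set (simulated when
    no matrices are passed) over the depth grid; emits data-point and
    per-individual yield accounting."""
    if gm is None or adm is None:
        truth, profile, err, adm = _simulate_deep(config)
        params = CallerParams(per_read_error=config.caller_error)
        gm = genotype_matrix(adm, truth.sites, params)
    depths = config.depths
    if config.population_class is PopulationClass.DOUBLED_HAPLOID:
        depths = tuple(sorted({1, *config.depths}))
    rows = []
    for d in depths:
        fp = _filter_preset(config, d)
        filtered, freport = apply_pipeline(gm, adm, fp)
        ys = yield_summary(filtered)
        rows.append(
            {
                "min_depth": d,
                "n_snps": freport.sites_out,
                "residual_missing_pct": round(100 * freport.residual_missing_fraction, 1),
                "total_data_points": freport.total_data_points,
                "n_missing_genotypes": freport.n_missing_genotypes,
                "yield_average": ys.average,
                "yield_min": ys.minimum,
                "yield_max": ys.maximum,
            }
        )
    return {"provenance": config.provenance(), "rows": rows}
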