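"""The site/cell filtering stack and its report arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skimeval.core_formats import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    SnpList,
    SnpSite,
)
from skimeval.filters import (
    FilterParams,
    MafRule,
    TriallelicPolicy,
    apply_pipeline,
    filter_het,
    filter_maf,
    filter_missing,
    handle_triallelic,
    mask_by_depth,
)

from conftest import make_adm, make_gm, make_samples, make_sites


class TestMaskByDepth:
    def test_zero_threshold_is_identity(self, rng):
        gm = make_gm(rng.integers(0, 3, (5, 4)))
        adm = make_adm(rng.integers(0, 5, (5, 4)))
        assert mask_by_depth(gm, adm, 0) == gm

    def test_all_shallow_cells_masked(self):
        gm = make_gm(np.full((3, 3), HOM_REF))
        adm = make_adm(np.ones((3, 3), dtype=int))
        out = mask_by_depth(gm, adm, 2)
        assert (out.codes == MISSING).all()

    def test_exactly_the_shallow_cells_masked(self):
        depths = np.arange(1, 10).reshape(3, 3)
        gm = make_gm(np.full((3, 3), HET))
        out = mask_by_depth(gm, make_adm(depths), 2)
        assert np.array_equal(out.codes == MISSING, depths < 2)

    def test_commutes_with_sample_permutation(self, rng):
        gm = make_gm(rng.integers(-1, 3, (6, 5)))
        adm = make_adm(rng.integers(0, 6, (6, 5)))
        perm = rng.permutation(5)
        direct = mask_by_depth(gm, adm, 3).codes[:, perm]
        permuted = mask_by_depth(
            make_gm(gm.codes[:, perm]), make_adm(adm.ref_reads[:, perm]), 3
        ).codes
        assert np.array_equal(direct, permuted)


class TestFilterMissing:
    def test_boundary_is_inclusive(self):
        codes = np.full((1, 10), HOM_REF)
        codes[0, :5] = MISSING  # exactly 0.5 missing
        assert filter_missing(make_gm(codes), 0.5).n_sites == 1

    def test_above_threshold_removed(self):
        codes = np.full((1, 10), HOM_REF)
        codes[0, :6] = MISSING
        assert filter_missing(make_gm(codes), 0.5).n_sites == 0

    def test_no_missing_is_identity(self, rng):
        gm = make_gm(rng.integers(0, 3, (8, 5)))
        assert filter_missing(gm, 0.0) == gm

    def test_relaxing_threshold_never_removes_a_kept_site(self, rng):
        gm = make_gm(rng.integers(-1, 3, (50, 10)))
        strict = filter_missing(gm, 0.3).sites.key_set()
        lenient = filter_missing(gm, 0.5).sites.key_set()
        assert strict <= lenient


class TestFilterMaf:
    def test_single_het_in_ten_samples_sits_on_the_threshold(self):
        # 9 HOM_REF + 1 HET: p = 1/20 = 0.05, retained at min_maf 0.05
        codes = np.array([[HOM_REF] * 9 + [HET]])
        assert filter_maf(make_gm(codes), 0.05).n_sites == 1

    def test_monomorphic_site_removed(self):
        codes = np.array([[HOM_REF] * 10])
        assert filter_maf(make_gm(codes), 0.05).n_sites == 0

    def test_any_group_rule_retains_on_one_passing_group(self):
        # group A monomorphic, group B at MAF 0.25
        codes = np.array([[HOM_REF] * 5 + [HOM_REF, HOM_REF, HET, HET, HOM_ALT]])
        groups = {"A": np.arange(5), "B": np.arange(5, 10)}
        assert filter_maf(make_gm(codes), 0.05, groups).n_sites == 1
        assert (
            filter_maf(make_gm(codes), 0.05, groups, rule=MafRule.ALL_GROUPS).n_sites
            == 0
        )

    def test_all_missing_site_removed(self):
        codes = np.full((1, 6), MISSING)
        assert filter_maf(make_gm(codes), 0.05).n_sites == 0

    def test_het_contributes_one_allele_each(self):
        # 10 samples all HET: p = 0.5 -> retained at any threshold <= 0.5
        codes = np.full((1, 10), HET)
        assert filter_maf(make_gm(codes), 0.5).n_sites == 1

    def test_empty_group_is_an_error(self):
        gm = make_gm(np.full((1, 4), HET))
        with pytest.raises(ValueError, match="empty"):
            filter_maf(gm, 0.05, {"A": np.array([], dtype=int)})


class TestFilterHet:
    def test_dh_matrix_unchanged(self, rng):
        gm = make_gm(rng.choice([HOM_REF, HOM_ALT], (20, 10)))
        assert filter_het(gm, 0.1) == gm

    def test_excess_het_removed_boundary_inclusive(self):
        two_het = np.array([[HET, HET] + [HOM_REF] * 8])
        one_het = np.array([[HET] + [HOM_REF] * 9])
        assert filter_het(make_gm(two_het), 0.1).n_sites == 0
        assert filter_het(make_gm(one_het), 0.1).n_sites == 1

    def test_missing_excluded_from_denominator(self):
        # 1 HET of 5 called (5 missing): fraction 0.2 > 0.1 -> removed
        codes = np.array([[HET] + [HOM_REF] * 4 + [MISSING] * 5])
        assert filter_het(make_gm(codes), 0.1).n_sites == 0


def tri_sites(n_bi, n_tri):
    sites = [SnpSite("chr1", 1 + i * 10, "A", ("C",)) for i in range(n_bi)]
    sites += [
        SnpSite("chr1", 1000 + i * 10, "A", ("C", "G")) for i in range(n_tri)
    ]
    return SnpList(sites)


class TestHandleTriallelic:
    def test_biallelic_input_identity_under_any_policy(self, rng):
        gm = make_gm(rng.integers(0, 3, (5, 3)))
        for policy in TriallelicPolicy:
            assert handle_triallelic(gm, None, policy) == gm

    def test_set_missing_keeps_row_but_masks_cells(self):
        sites = tri_sites(2, 1)
        gm = make_gm(np.full((3, 4), HOM_ALT), sites=sites)
        out = handle_triallelic(gm, None, TriallelicPolicy.SET_MISSING)
        assert out.n_sites == 3
        tri_row = [i for i, s in enumerate(out.sites) if not s.is_biallelic]
        assert (out.codes[tri_row] == MISSING).all()
        bi_rows = [i for i, s in enumerate(out.sites) if s.is_biallelic]
        assert (out.codes[bi_rows] == HOM_ALT).all()

    def test_drop_site_removes_row(self):
        sites = tri_sites(2, 1)
        gm = make_gm(np.full((3, 4), HOM_REF), sites=sites)
        out = handle_triallelic(gm, None, TriallelicPolicy.DROP_SITE)
        assert out.n_sites == 2
        assert all(s.is_biallelic for s in out.sites)

    def test_unknown_policy_rejected(self):
        gm = make_gm(np.full((1, 2), HOM_REF))
        with pytest.raises(ValueError):
            handle_triallelic(gm, None, "purge")


class TestApplyPipeline:
    def test_disabled_params_are_identity(self, rng):
        gm = make_gm(rng.integers(-1, 3, (10, 5)))
        adm = make_adm(rng.integers(0, 8, (10, 5)))
        params = FilterParams(
            min_depth=0, max_missing=None, min_maf=None, max_het=None,
            triallelic_policy=TriallelicPolicy.KEEP,
        )
        out, report = apply_pipeline(gm, adm, params)
        assert out == gm
        assert sum(report.sites_removed_per_rule.values()) == 0

    def test_report_counts_match_hand_enumeration(self):
        # 6 sites x 4 samples engineered so each rule claims known sites
        sites = tri_sites(5, 1)  # last site triallelic
        codes = np.array(
            [
                [HOM_REF, HET, HOM_ALT, HOM_REF],   # survives everything
                [HOM_REF, HOM_REF, HOM_REF, HET],   # survives (maf 1/8, het 1/4? -> removed by het)
                [HOM_REF, HOM_REF, HOM_REF, HOM_REF],  # monomorphic -> maf
                [HET, HET, HOM_REF, HOM_REF],       # het fraction 0.5 -> het
                [HOM_REF, HOM_ALT, MISSING, MISSING],  # depth masks 2 more -> missing
                [HOM_REF, HET, HOM_ALT, HOM_REF],   # triallelic
            ],
            dtype=np.int8,
        )
        depth = np.full((6, 4), 5)
        depth[4, 0] = 1  # masked, site 4 then 3/4 missing
        gm = make_gm(codes, sites=sites, samples=make_samples(4))
        adm = make_adm(depth, sites=sites, samples=make_samples(4))
        params = FilterParams(
            min_depth=2, max_missing=0.5, min_maf=0.05, max_het=0.25,
            triallelic_policy=TriallelicPolicy.DROP_SITE,
        )
        out, report = apply_pipeline(gm, adm, params)
        assert report.sites_in == 6
        assert report.sites_removed_per_rule == {
            "triallelic": 1, "missing": 1, "maf": 1, "het": 1,
        }
        assert report.sites_out == 2
        assert report.total_data_points == 8
        report.validate()

    def test_pipeline_is_idempotent(self, rng):
        gm = make_gm(rng.integers(-1, 3, (100, 12)))
        adm = make_adm(
            rng.integers(0, 6, (100, 12)), rng.integers(0, 3, (100, 12))
        )
        params = FilterParams.diversity_panel(min_depth=2)
        once, _ = apply_pipeline(gm, adm, params)
        keys = once.sites.key_set()
        mask = np.array([s.key in keys for s in adm.sites])
        twice, report2 = apply_pipeline(once, adm.subset_sites(mask), params)
        assert twice == once
        assert sum(report2.sites_removed_per_rule.values()) == 0

    def test_site_yield_monotone_in_depth(self, rng):
        gm = make_gm(rng.integers(0, 3, (200, 10)))
        adm = make_adm(rng.poisson(2.5, (200, 10)), rng.poisson(0.5, (200, 10)))
        outs = []
        for d in (0, 1, 2, 3, 4, 5):
            filtered, _ = apply_pipeline(
                gm, adm, FilterParams.diversity_panel(min_depth=d)
            )
            outs.append(filtered.n_sites)
        assert all(a >= b for a, b in zip(outs, outs[1:]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 30), st.integers(2, 8))
    def test_report_accounting_always_balances(self, seed, n_sites, n_samples):
        rng = np.random.default_rng(seed)
        gm = make_gm(rng.integers(-1, 3, (n_sites, n_samples)),
                     samples=make_samples(n_samples))
        adm = make_adm(rng.integers(0, 6, (n_sites, n_samples)),
                       samples=make_samples(n_samples))
        _, report = apply_pipeline(gm, adm, FilterParams.diversity_panel(min_depth=2))
        report.validate()
        assert report.total_data_points == report.sites_out * n_samples


class TestPresets:
    def test_dh_preset_disables_site_filters(self):
        p = FilterParams.doubled_haploid(min_depth=1)
        assert p.max_missing is None and p.min_maf is None and p.max_het is None
        assert p.triallelic_policy is TriallelicPolicy.SET_MISSING

    def test_four_parent_preset_maf(self):
        p = FilterParams.four_parent(min_depth=4)
        assert p.min_maf == 0.01 and p.max_missing == 0.5 and p.max_het is None
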