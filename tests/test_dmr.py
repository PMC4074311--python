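import numpy as np
import pandas as pd
import pytest

from methylshift.dmr import (
    FdrCurve,
    ThresholdSelectionError,
    call_dmrs,
    fdr_curve,
    fragment_z,
    select_extreme_dmrs,
    select_threshold,
    simulate_null,
    site_tests,
)
from methylshift.fragments import fragments_from_gaps
from methylshift.io import common_sites
from tests.conftest import cg_keys, make_sample, pick, sample_from_levels, site_index


def two_group_samples(levels_a, levels_b, positions=None, coverage=100):
    """Two replicate samples per group with exact observed levels."""
    positions = positions or list(range(0, 40 * len(levels_a[0]), 40))
    sa = [sample_from_levels(positions, lv, coverage, sample_id=f"a{i}", group="XX")
          for i, lv in enumerate(levels_a)]
    sb = [sample_from_levels(positions, lv, coverage, sample_id=f"b{i}", group="XY")
          for i, lv in enumerate(levels_b)]
    return sa, sb


class TestSiteTests:
    def test_hand_computed_levels(self):
        # XX reps at 0.1/0.2, XY reps at 0.8/0.9:
        # delta = -0.7, sp^2 = 0.005, t = -0.7/sqrt(0.005) = -9.8995
        sa, sb = two_group_samples([[0.1], [0.2]], [[0.8], [0.9]])
        tests = site_tests(sa, sb)
        assert tests["delta"].iloc[0] == pytest.approx(-0.7)
        assert tests["t"].iloc[0] == pytest.approx(-9.8994949, abs=1e-5)

    def test_identical_groups_give_zero_t(self):
        sa, sb = two_group_samples([[0.3], [0.5]], [[0.3], [0.5]])
        assert site_tests(sa, sb)["t"].iloc[0] == 0.0

    def test_site_missing_in_one_replicate_is_dropped(self):
        sa, sb = two_group_samples([[0.1, 0.2], [0.2, 0.3]], [[0.8, 0.9], [0.9, 0.8]],
                                   positions=[0, 40])
        # remove the second site from one replicate
        sb[1] = sb[1].with_sites(sb[1].sites.iloc[:1])
        keys = site_index([("chr1", 0, "+"), ("chr1", 40, "+")])
        tests = site_tests(sa, sb, keys)
        assert list(tests.index) == [("chr1", 0, "+")]
        assert list(tests.attrs["dropped"]) == [("chr1", 40, "+")]

    def test_requires_two_replicates(self):
        sa, sb = two_group_samples([[0.1], [0.2]], [[0.8], [0.9]])
        with pytest.raises(ValueError):
            site_tests(sa[:1], sb)


class TestFragmentZ:
    def test_z_is_mean_of_member_t_scores(self):
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        frags.index.name = "frag_id"
        tests = pd.DataFrame(
            {"t": [2.0, 4.0], "delta": [0.2, 0.4], "mean_a": [0.5, 0.6],
             "mean_b": [0.3, 0.2], "p": [0.1, 0.1]},
            index=site_index([("chr1", 10, "+"), ("chr1", 20, "+")]),
        )
        ft = fragment_z(frags, tests)
        assert ft["z"].iloc[0] == pytest.approx(3.0)
        assert ft["delta"].iloc[0] == pytest.approx(0.3)
        assert ft["n_obs_sites"].iloc[0] == 2

    def test_single_site_fragment_z_equals_t(self):
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        tests = pd.DataFrame(
            {"t": [-5.0], "delta": [-0.3], "mean_a": [0.2], "mean_b": [0.5], "p": [0.05]},
            index=site_index([("chr1", 10, "+")]),
        )
        assert fragment_z(frags, tests)["z"].iloc[0] == -5.0

    def test_opposite_t_scores_cancel(self):
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        tests = pd.DataFrame(
            {"t": [-3.0, 3.0], "delta": [-0.1, 0.1], "mean_a": [0.2, 0.5],
             "mean_b": [0.3, 0.4], "p": [0.1, 0.1]},
            index=site_index([("chr1", 10, "+"), ("chr1", 20, "+")]),
        )
        assert fragment_z(frags, tests)["z"].iloc[0] == 0.0

    def test_fragment_without_tested_sites_omitted(self):
        frags = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 200], "end": [100, 300]})
        tests = pd.DataFrame(
            {"t": [1.0], "delta": [0.1], "mean_a": [0.5], "mean_b": [0.4], "p": [0.3]},
            index=site_index([("chr1", 10, "+")]),
        )
        assert list(fragment_z(frags, tests).index) == [0]


def frag_test_row(z=4.0, delta=0.2, n=3, start=0, end=100):
    return {"chrom": "chr1", "start": start, "end": end, "n_obs_sites": n,
            "z": z, "delta": delta, "mean_a": 0.5, "mean_b": 0.5 - delta}


class TestCalling:
    def test_three_filters(self):
        ft = pd.DataFrame([
            frag_test_row(z=4.0, delta=0.2, n=3),    # passes all
            frag_test_row(z=4.0, delta=0.5, n=2),    # too few sites
            frag_test_row(z=4.0, delta=0.05, n=5),   # delta too small
            frag_test_row(z=1.0, delta=0.5, n=5),    # z too mild
            frag_test_row(z=-4.0, delta=-0.10, n=3), # boundary delta, negative direction
        ])
        dmrs = call_dmrs(ft, z_threshold=3.0)
        assert sorted(dmrs.index) == [0, 4]
        assert dmrs.loc[0, "direction"] == "hyper_in_A"
        assert dmrs.loc[4, "direction"] == "hypo_in_A"

    def test_called_dmrs_are_subset_of_fragments(self):
        rng = np.random.default_rng(0)
        ft = pd.DataFrame([frag_test_row(z=z, delta=d, n=n) for z, d, n in
                           zip(rng.normal(0, 3, 50), rng.normal(0, 0.2, 50),
                               rng.integers(1, 8, 50))])
        dmrs = call_dmrs(ft, 2.0)
        assert set(dmrs.index) <= set(ft.index)

    def test_extreme_dmr_selection(self):
        dmrs = pd.DataFrame([
            frag_test_row(z=-4.0, delta=0.30, end=60),   # retained
            frag_test_row(z=-4.0, delta=0.30, end=40),   # too short
            frag_test_row(z=-4.0, delta=0.20, end=60),   # delta below 25%
            frag_test_row(z=-3.0, delta=0.30, end=60),   # |z| below 3.5
        ])
        assert list(select_extreme_dmrs(dmrs).index) == [0]


class TestSimulateNull:
    def _samples(self, level, coverage=50, n_sites=30):
        return [sample_from_levels(range(0, n_sites * 40, 40), [level] * n_sites,
                                   coverage, sample_id=f"s{i}") for i in range(4)]

    def test_pm_zero_and_one_endpoints(self):
        for level, expected in ((0.0, 0), (1.0, 1)):
            sims = simulate_null(self._samples(level), seed=1)
            for s in sims:
                lv = s.levels()
                assert (lv == expected).all()

    def test_coverage_preserved_exactly(self):
        samples = self._samples(0.5)
        sims = simulate_null(samples, seed=2)
        for orig, sim in zip(samples, sims):
            assert (orig.coverage() == sim.coverage()).all()

    def test_simulated_mean_close_to_pm(self):
        # total 4 samples x 250 sites x 100 reads = 100k draws at Pm=0.5
        samples = self._samples(0.5, coverage=100, n_sites=250)
        sims = simulate_null(samples, seed=3)
        pooled = np.mean([s.levels().mean() for s in sims])
        se = np.sqrt(0.25 / (4 * 250 * 100))
        assert abs(pooled - 0.5) < 3 * se

    def test_deterministic_under_seed(self):
        samples = self._samples(0.3)
        a = simulate_null(samples, seed=7)
        b = simulate_null(samples, seed=7)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.sites, y.sites)


class TestFdr:
    def test_ratio_and_conventions(self):
        curve = FdrCurve(np.array([1.0]), np.array([100.0]), np.array([5.0]),
                         np.array([0.05]))
        assert curve.fdr[0] == 0.05
        # conventions are produced inside fdr_curve; emulate its formula
        n_real = np.array([0.0, 0.0, 10.0])
        n_sim = np.array([3.0, 0.0, 0.0])
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr = n_sim / n_real
        fdr = np.where(n_real > 0, fdr, np.where(n_sim > 0, 1.0, 0.0))
        assert fdr.tolist() == [1.0, 0.0, 0.0]

    def test_select_threshold_first_below_target(self):
        curve = FdrCurve(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4), np.ones(4),
                         np.array([0.5, 0.2, 0.08, 0.01]))
        assert select_threshold(curve, 0.10) == 3.0

    def test_select_threshold_all_pass_and_none_pass(self):
        ok = FdrCurve(np.array([1.0, 2.0]), np.ones(2), np.zeros(2), np.array([0.01, 0.0]))
        assert select_threshold(ok, 0.10) == 1.0
        bad = FdrCurve(np.array([1.0, 2.0]), np.ones(2), np.ones(2), np.array([0.5, 0.2]))
        with pytest.raises(ThresholdSelectionError):
            select_threshold(bad, 0.10)

    def test_empty_grid_rejected(self, null_cohort):
        _, samples, _ = null_cohort
        sa = pick(samples, "XX", "PN60", "STR")
        sb = pick(samples, "XY", "PN60", "STR")
        keys = cg_keys(sa + sb)
        frags = fragments_from_gaps(keys)
        with pytest.raises(ValueError):
            fdr_curve(sa, sb, frags, keys, thresholds=[])

    def test_counts_monotone_in_cutoff(self, small_cohort):
        _, samples, _ = small_cohort
        sa = pick(samples, "XX", "PN60", "STR")
        sb = pick(samples, "XY", "PN60", "STR")
        keys = cg_keys(sa + sb)
        frags = fragments_from_gaps(keys)
        curve = fdr_curve(sa, sb, frags, keys, seed=5)
        assert (np.diff(curve.n_real) <= 0).all()
        assert (np.diff(curve.n_sim) <= 0).all()

    def test_null_cohort_exchangeability(self, null_cohort):
        """With no implanted effects and no delta filter, real and simulated
        DMR counts agree, so the FDR estimate sits near 1 at lenient cutoffs."""
        _, samples, _ = null_cohort
        sa = pick(samples, "XX", "PN60", "STR")
        sb = pick(samples, "XXT", "PN60", "STR")
        keys = cg_keys(sa + sb)
        frags = fragments_from_gaps(keys)
        curve = fdr_curve(sa, sb, frags, keys, thresholds=[0.25, 0.5],
                          min_delta=0.0, min_sites=1, seed=17, n_sim_reps=3)
        assert curve.n_real[0] > 200
        assert curve.fdr[0] == pytest.approx(1.0, abs=0.15)

    def test_deterministic_dmr_table(self, small_cohort):
        _, samples, _ = small_cohort
        sa = pick(samples, "XX", "PN60", "STR")
        sb = pick(samples, "XY", "PN60", "STR")
        keys = cg_keys(sa + sb)
        frags = fragments_from_gaps(keys)

        def run_once():
            tests = site_tests(sa, sb, keys)
            curve = fdr_curve(sa, sb, frags, keys, seed=31, real_tests=tests)
            th = select_threshold(curve)
            return call_dmrs(fragment_z(frags, tests), th)

        pd.testing.assert_frame_equal(run_once(), run_once())
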