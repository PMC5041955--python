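import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mirmix as mm
from mirmix import survival
from conftest import make_matrix


class TestKaplanMeier:
    def test_no_censoring_is_empirical_survival(self):
        km = mm.km_estimate([1, 2, 3], [1, 1, 1])
        assert survival.survival_at(km, 1) == pytest.approx(2 / 3)
        assert survival.survival_at(km, 2) == pytest.approx(1 / 3)
        assert survival.survival_at(km, 3) == pytest.approx(0.0)

    def test_all_censored_flat_one(self):
        km = mm.km_estimate([4, 5, 6], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_hand_product_limit_with_censoring(self):
        # times (1, 2+, 3): S = 2/3 on [1,3), then (2/3)*(1 - 1/1) = 0
        km = mm.km_estimate([1, 2, 3], [1, 0, 1])
        assert survival.survival_at(km, 1.5) == pytest.approx(2 / 3)
        assert survival.survival_at(km, 2.5) == pytest.approx(2 / 3)
        assert survival.survival_at(km, 3) == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mm.km_estimate([], [])

    def test_step_function_properties(self):
        rng = np.random.default_rng(0)
        km = mm.km_estimate(rng.exponential(10, 50), rng.integers(0, 2, 50))
        s = km["survival"].to_numpy()
        assert s[0] == 1.0 or km["time"].iloc[0] == 0.0
        assert (np.diff(s) <= 1e-12).all()


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 1, 1, 1, 1, 1, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        res = mm.logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_table(self):
        # A events at 1,2; B events at 3,4. By hand:
        # t=1: E_A += 2/4, V += (2/4)(2/4) = 1/4
        # t=2: E_A += 1/3, V += (1/3)(2/3) = 2/9
        # t=3: E_A += 0 (A exhausted); t=4 single at risk contributes 0
        # O-E = 2 - 5/6, V = 17/36 -> chi2 = (7/6)^2/(17/36) = 49/17
        res = mm.logrank_test([1, 2, 3, 4], [1, 1, 1, 1], [0, 0, 1, 1])
        assert res.statistic == pytest.approx(49 / 17, rel=1e-6)
        assert res.p == pytest.approx(stats.chi2.sf(49 / 17, 1), rel=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            mm.logrank_test([1, 2], [1, 1], [0, 0])

    def test_matches_permutation_null(self):
        """The chi-square p agrees with a 10,000-permutation label null."""
        rng = np.random.default_rng(12)
        n = 40
        times = rng.exponential(10, n)
        events = (rng.uniform(size=n) < 0.8).astype(int)
        groups = (rng.uniform(size=n) < 0.5).astype(int)
        obs = mm.logrank_test(times, events, groups)
        order = np.argsort(times, kind="stable")
        ts, es = times[order], events[order]
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            gp = rng.permutation(groups)[order].astype(bool)
            if survival._logrank_p_fast(ts, es, gp) <= obs.p + 1e-12:
                count += 1
        assert count / n_perm == pytest.approx(obs.p, abs=0.01)

    def test_time_scale_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 30)
        e = rng.integers(0, 2, 30)
        g = rng.integers(0, 2, 30)
        if len(np.unique(g)) < 2:
            g[0] = 1 - g[0]
        p1 = mm.logrank_test(t, e, g).p
        p2 = mm.logrank_test(t * 123.4, e, g).p
        assert p1 == pytest.approx(p2)

    def test_fast_scan_agrees_with_lifelines(self):
        rng = np.random.default_rng(7)
        n = 60
        times = rng.exponential(20, n)
        events = (rng.uniform(size=n) < 0.7).astype(int)
        order = np.argsort(times, kind="stable")
        for trial in range(10):
            g = rng.uniform(size=n) < rng.uniform(0.2, 0.8)
            if g.all() or not g.any():
                continue
            p_fast = survival._logrank_p_fast(times[order], events[order], g[order])
            p_ll = mm.logrank_test(times, events, g).p
            assert p_fast == pytest.approx(p_ll, rel=1e-9)


class TestOptimalCutoff:
    def test_recovers_planted_threshold(self):
        values, times, events = mm.generate_threshold_survival(
            n=200, threshold_quantile=0.5, hazard_ratio=2.0, seed=4
        )
        res = mm.optimal_cutoff(values, times, events)
        assert res.found
        lo, hi = np.quantile(values, [0.4, 0.6])
        assert lo <= res.cutoff <= hi

    def test_constant_covariate_no_cutoff(self):
        rng = np.random.default_rng(0)
        res = mm.optimal_cutoff(np.ones(20), rng.exponential(5, 20), np.ones(20))
        assert not res.found and res.p is None

    def test_monotone_transform_same_split(self):
        values, times, events = mm.generate_threshold_survival(n=60, seed=9)
        r1 = mm.optimal_cutoff(values, times, events)
        r2 = mm.optimal_cutoff(np.exp(values), times, events)
        assert r1.p == pytest.approx(r2.p)
        assert (r1.n_low, r1.n_high) == (r2.n_low, r2.n_high)

    def test_group_size_constraint_respected(self):
        values, times, events = mm.generate_threshold_survival(n=50, seed=2)
        res = mm.optimal_cutoff(values, times, events, min_group_frac=0.2)
        assert min(res.n_low, res.n_high) >= 10

    def test_null_scan_fdr_control(self):
        """Scanning many null covariates is anti-conservative per covariate;
        BH across covariates keeps the q<0.05 fraction near nominal."""
        rng = np.random.default_rng(21)
        n = 60
        times = rng.exponential(10, n)
        events = (rng.uniform(size=n) < 0.7).astype(int)
        clin = mm.ClinicalTable(
            pd.DataFrame(
                {"os_time": times, "os_event": events},
                index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
            )
        )
        n_vars = 1000
        variables = pd.DataFrame(
            rng.standard_normal((n, n_vars)),
            index=clin.sample_ids,
            columns=[f"v{i}" for i in range(n_vars)],
        )
        table = survival.cutoff_scan_table(variables, clin)
        assert (table["q"] < 0.05).mean() <= 0.10


class TestDifferential:
    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((1000, 60))
        m = make_matrix(np.abs(X), unit="RPM")
        groups = np.repeat([0, 1, 2], 20)
        out = mm.differential_by_outcome(m, groups)
        assert (out["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.03)

    def test_shifted_feature_detected(self):
        rng = np.random.default_rng(9)
        X = np.abs(rng.standard_normal((50, 60))) + 1
        groups = np.repeat([0, 1], 30)
        X[0, groups == 1] += 3 * X[0].std()
        out = mm.differential_by_outcome(make_matrix(X, unit="RPM"), groups)
        assert out.loc[0, "q"] < 0.05

    def test_two_group_equals_wilcoxon_chi2_form(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(1, 5, 30)
        groups = rng.integers(0, 2, 30)
        if len(np.unique(groups)) < 2:
            groups[0] = 1 - groups[0]
        out = mm.differential_by_outcome(make_matrix([x], unit="RPM"), groups)
        kw = stats.kruskal(x[groups == 0], x[groups == 1])
        assert out.loc[0, "p"] == pytest.approx(kw.pvalue)
        # K-W with 2 groups is the chi-square form of the rank-sum test
        mw = stats.mannwhitneyu(x[groups == 0], x[groups == 1], method="asymptotic")
        assert out.loc[0, "p"] == pytest.approx(mw.pvalue, rel=0.05)


@pytest.fixture(scope="module")
def prognostic_cohort():
    """Two planted miRNAs jointly index a high-hazard patient cluster."""
    rng = np.random.default_rng(14)
    n = 120
    member = rng.uniform(size=n) < 0.4
    X = np.abs(rng.standard_normal((5, n))) + 1.0
    X[0, member] += 4.0
    X[1, member] += 4.0
    rate = 0.02 * np.where(member, 4.0, 1.0)
    times = rng.exponential(1.0 / rate)
    events = (rng.uniform(size=n) < 0.8).astype(int)
    mirs = make_matrix(X, unit="RPM", prefix="mir")
    clin = mm.ClinicalTable(
        pd.DataFrame(
            {"os_time": times, "os_event": events},
            index=pd.Index(mirs.sample_ids, name="sample_id"),
        )
    )
    return mirs, clin


class TestSubsetSearch:
    def test_subset_count(self, prognostic_cohort):
        mirs, clin = prognostic_cohort
        out = mm.subset_survival_search(mirs.subset_features(["mir0", "mir1", "mir2"]), clin, seed=0)
        assert len(out) == 7  # 2^3 - 1

    def test_planted_pair_ranks_first(self, prognostic_cohort):
        mirs, clin = prognostic_cohort
        out = mm.subset_survival_search(mirs, clin, seed=0)
        top = set(out.loc[0, "members"].split(","))
        assert {"mir0", "mir1"} <= top

    def test_deterministic(self, prognostic_cohort):
        mirs, clin = prognostic_cohort
        a = mm.subset_survival_search(mirs, clin, seed=5)
        b = mm.subset_survival_search(mirs, clin, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_universe_cap(self, prognostic_cohort):
        mirs, clin = prognostic_cohort
        with pytest.raises(ValueError, match="cap"):
            mm.subset_survival_search(mirs, clin, max_universe=3)

    def test_double_normalization_ranges(self, prognostic_cohort):
        mirs, _ = prognostic_cohort
        normed = survival.double_normalize(mirs.data)
        assert normed.min(axis=1).le(1e-12).all()
        assert normed.max(axis=1).sub(1).abs().le(1e-12).all()
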