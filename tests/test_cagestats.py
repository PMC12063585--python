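"""Tests of the cage-level GLMs, contrasts, and climate statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logit

import cagesym as cs


def _bugs(cage, treatment, stages, alive=None, positive=None, year=2019):
    n = len(stages)
    return pd.DataFrame(
        {
            "bug_id": [f"{cage}_b{i}" for i in range(n)],
            "cage_id": cage,
            "origin": "caged",
            "treatment": treatment,
            "year": year,
            "stage": stages,
            "sex": "unknown",
            "alive": alive if alive is not None else [True] * n,
            "symbiont_positive": positive if positive is not None else [True] * n,
        }
    )


def _summaries(spec):
    """spec: list of (cage, treatment, n_pos, n_tested[, n_dead])"""
    rows = []
    for item in spec:
        cage, trt, pos, tested = item[:4]
        dead = item[4] if len(item) > 4 else 0
        rows.append(
            {
                "cage_id": cage, "treatment": trt, "year": 2019,
                "n_tested": tested, "n_positive": pos, "n_late": pos,
                "n_dead": dead, "n_recovered": tested, "n_alive": tested - dead,
            }
        )
    return pd.DataFrame(rows)


class TestFilters:
    def test_overfull_cage_excluded_boundary_retained(self):
        bugs = pd.concat(
            [
                _bugs("c13", "t", ["adult"] * 13),
                _bugs("c12", "t", ["adult"] * 12),
                _bugs("c03", "t", ["adult"] * 3),
            ]
        )
        cages = pd.DataFrame({"cage_id": ["c13", "c12", "c03"], "treatment": "t"})
        fc, fb = cs.exclude_overfull_cages(cages, bugs)
        assert set(fc["cage_id"]) == {"c12", "c03"}
        assert "c13" not in set(fb["cage_id"])

    def test_no_cage_exceeds_cap(self):
        bugs = _bugs("c1", "t", ["adult"] * 5)
        cages = pd.DataFrame({"cage_id": ["c1"], "treatment": "t"})
        fc, fb = cs.exclude_overfull_cages(cages, bugs)
        pd.testing.assert_frame_equal(fb, bugs)

    @pytest.mark.parametrize(
        "stage,expected",
        [("instar3", "early"), ("instar4", "early"), ("instar5", "late"), ("adult", "late")],
    )
    def test_stage_class(self, stage, expected):
        assert cs.stage_class(stage) == expected

    def test_second_instar_has_no_class(self):
        with pytest.raises(ValueError):
            cs.stage_class("instar2")


class TestSummarizeCages:
    def test_simple_tally(self):
        bugs = _bugs(
            "c1", "t", ["adult"] * 7, positive=[True] * 5 + [False] * 2
        )
        s = cs.summarize_cages(bugs)
        assert s.loc[0, "n_positive"] == 5 and s.loc[0, "n_tested"] == 7

    def test_late_counted_over_survivors_only(self):
        bugs = _bugs(
            "c1", "t", ["adult", "adult", "instar3", "instar5"],
            alive=[False, True, True, True],
        )
        s = cs.summarize_cages(bugs)
        assert s.loc[0, "n_late"] == 2  # dead adult not counted
        assert s.loc[0, "n_dead"] == 1 and s.loc[0, "n_alive"] == 3

    def test_random_tables_match_brute_tally(self):
        rng = np.random.default_rng(0)
        frames = []
        for c in range(6):
            n = int(rng.integers(3, 12))
            frames.append(
                _bugs(
                    f"c{c}", f"t{c % 2}",
                    list(rng.choice(["instar3", "instar4", "instar5", "adult"], n)),
                    alive=list(rng.random(n) > 0.2),
                    positive=list(rng.random(n) > 0.5),
                )
            )
        bugs = pd.concat(frames)
        s = cs.summarize_cages(bugs).set_index("cage_id")
        for cage, grp in bugs.groupby("cage_id"):
            assert s.loc[cage, "n_positive"] == grp["symbiont_positive"].sum()
            assert s.loc[cage, "n_dead"] == (~grp["alive"]).sum()
            live = grp[grp["alive"]]
            assert s.loc[cage, "n_late"] == live["stage"].isin(["instar5", "adult"]).sum()


class TestBinomialFit:
    def test_single_group_intercept_is_pooled_logit(self):
        s = _summaries([("c1", "t", 3, 10), ("c2", "t", 6, 10)])
        fit = cs.fit_binomial_props(s, "positive")
        assert fit.coefficients["t"] == pytest.approx(logit(9 / 20), abs=1e-6)
        assert np.isnan(fit.statistic)

    def test_matches_statsmodels_quasibinomial(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(1)
        rows = []
        for trt, p in [("a", 0.7), ("b", 0.3), ("c", 0.4)]:
            for c in range(8):
                n = 12
                rows.append((f"{trt}{c}", trt, int(rng.binomial(n, p)), n))
        s = _summaries(rows)
        fit = cs.fit_binomial_props(s, "positive")
        y = s["n_positive"].to_numpy(float)
        n = s["n_tested"].to_numpy(float)
        X = pd.get_dummies(s["treatment"]).to_numpy(float)
        res = sm.GLM(np.c_[y, n - y], X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coefficients.to_numpy(), res.params, atol=1e-6)
        np.testing.assert_allclose(fit.deviance, res.deviance, atol=1e-6)
        disp_sm = res.pearson_chi2 / res.df_resid
        assert fit.dispersion == pytest.approx(disp_sm, rel=1e-6)
        # treatment F-test against statsmodels' null deviance
        res0 = sm.GLM(
            np.c_[y, n - y], np.ones((len(s), 1)), family=sm.families.Binomial()
        ).fit()
        f_sm = ((res0.deviance - res.deviance) / 2) / disp_sm
        assert fit.statistic == pytest.approx(f_sm, rel=1e-6)

    def test_parameter_recovery_2019_design(self):
        # control acquires at 0.75, three open treatments at 0.30
        rng = np.random.default_rng(2)
        probs = {"control": 0.75, "t1": 0.30, "t2": 0.30, "t3": 0.30}
        ok = {t: 0 for t in probs}
        for _ in range(100):
            rows = [
                (f"{t}{c}", t, int(rng.binomial(12, p)), 12)
                for t, p in probs.items() for c in range(10)
            ]
            fit = cs.fit_binomial_props(_summaries(rows), "positive")
            for t, p in probs.items():
                ok[t] += abs(fit.fitted[t] - p) <= 0.10
        assert all(v >= 95 for v in ok.values())

    def test_dispersion_near_one_without_overdispersion(self):
        rng = np.random.default_rng(3)
        disps = []
        for _ in range(200):
            rows = [
                (f"{t}{c}", t, int(rng.binomial(20, p)), 20)
                for t, p in [("a", 0.6), ("b", 0.4)] for c in range(15)
            ]
            disps.append(cs.fit_binomial_props(_summaries(rows), "positive").dispersion)
        assert np.mean(disps) == pytest.approx(1.0, abs=0.05)

    def test_complete_separation_flagged(self):
        s = _summaries([("c1", "a", 0, 10), ("c2", "a", 0, 10),
                        ("c3", "b", 5, 10), ("c4", "b", 6, 10)])
        fit = cs.fit_binomial_props(s, "positive")
        assert "a" in fit.boundary_levels
        assert any("separation" in w for w in fit.warnings)


class TestPoissonFit:
    def test_single_group_rate_is_mean(self):
        s = _summaries([("c1", "t", 0, 10, 2), ("c2", "t", 0, 10, 4)])
        fit = cs.fit_poisson_counts(s)
        assert fit.fitted["t"] == pytest.approx(3.0, abs=1e-8)
        assert fit.coefficients["t"] == pytest.approx(np.log(3.0), abs=1e-8)

    def test_lrt_equals_direct_likelihood_oracle(self):
        rng = np.random.default_rng(4)
        rows = [
            (f"{t}{c}", t, 0, 12, int(rng.poisson(lam)))
            for t, lam in [("a", 1.0), ("b", 3.0)] for c in range(10)
        ]
        s = _summaries(rows)
        fit = cs.fit_poisson_counts(s)
        y = s["n_dead"].to_numpy(float)
        grp = s["treatment"].to_numpy()
        ll_full = sum(
            stats.poisson.logpmf(y[grp == g], y[grp == g].mean()).sum()
            for g in ("a", "b")
        )
        ll_null = stats.poisson.logpmf(y, y.mean()).sum()
        assert fit.statistic == pytest.approx(2 * (ll_full - ll_null), abs=1e-6)

    def test_recovers_rates_and_detects_difference(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(100):
            rows = [
                (f"{t}{c}", t, 0, 12, int(rng.poisson(lam)))
                for t, lam in [("a", 1.0), ("b", 3.0)] for c in range(10)
            ]
            fit = cs.fit_poisson_counts(_summaries(rows))
            if fit.p_value < 0.05:
                hits += 1
        assert hits >= 90

    def test_matches_statsmodels_poisson(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        rows = [
            (f"{t}{c}", t, 0, 12, int(rng.poisson(lam)))
            for t, lam in [("a", 0.5), ("b", 2.0), ("c", 1.0)] for c in range(8)
        ]
        s = _summaries(rows)
        fit = cs.fit_poisson_counts(s)
        X = pd.get_dummies(s["treatment"]).to_numpy(float)
        res = sm.GLM(s["n_dead"].to_numpy(float), X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.coefficients.to_numpy(), res.params, atol=1e-6)
        np.testing.assert_allclose(fit.deviance, res.deviance, atol=1e-8)

    def test_all_zero_level_flagged(self):
        s = _summaries([("c1", "a", 0, 10, 0), ("c2", "a", 0, 10, 0),
                        ("c3", "b", 0, 10, 3)])
        fit = cs.fit_poisson_counts(s)
        assert "a" in fit.boundary_levels


class TestContrasts:
    def test_holm_formula(self):
        np.testing.assert_allclose(
            cs.holm_adjust([0.01, 0.04, 0.30]), [0.03, 0.08, 0.30]
        )

    def test_holm_matches_statsmodels_and_is_monotone(self):
        multipletests = pytest.importorskip("statsmodels.stats.multitest").multipletests
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(2, 10)))
            ours = cs.holm_adjust(p)
            theirs = multipletests(p, method="holm")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)
            assert (ours >= p - 1e-15).all()
            order = np.argsort(p)
            assert (np.diff(ours[order]) >= -1e-15).all()

    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(8)
        rows = [
            (f"{t}{c}", t, int(rng.binomial(12, 0.5)), 12)
            for t in ("a", "b") for c in range(10)
        ]
        fit = cs.fit_binomial_props(_summaries(rows), "positive")
        table, letters = cs.pairwise_contrasts(fit)
        assert table.loc[0, "p_holm"] > 0.4
        assert letters["a"] == letters["b"]

    def test_letter_pattern_control_vs_low_groups(self):
        # generating probabilities (0.75, 0.04, 0.04): the fed control is
        # separated from both open treatments, which share a letter
        rng = np.random.default_rng(9)
        probs = {"control": 0.75, "open1": 0.20, "open2": 0.20}
        rows = [
            (f"{t}{c}", t, int(rng.binomial(12, p)), 12)
            for t, p in probs.items() for c in range(10)
        ]
        fit = cs.fit_binomial_props(_summaries(rows), "positive")
        _, letters = cs.pairwise_contrasts(fit)
        assert letters["open1"] == letters["open2"]
        assert set(letters["control"]) & set(letters["open1"]) == set()

    def test_boundary_contrast_indeterminate(self):
        s = _summaries([("c1", "a", 0, 10), ("c2", "a", 0, 10),
                        ("c3", "b", 5, 10), ("c4", "b", 6, 10)])
        fit = cs.fit_binomial_props(s, "positive")
        table, _ = cs.pairwise_contrasts(fit)
        assert table["indeterminate"].all()

    def test_compact_letters_three_groups(self):
        letters = cs.compact_letters(["a", "b", "c"], [("a", "b"), ("a", "c")])
        assert letters["b"] == letters["c"]
        assert set(letters["a"]) & set(letters["b"]) == set()


class TestClimate:
    def test_daily_maxima_constant_series(self):
        ts = pd.date_range("2020-01-01", periods=48, freq="h")
        s = pd.DataFrame({"timestamp": ts, "temperature": 20.0, "humidity": 50.0})
        out = cs.daily_maxima(s)
        assert len(out) == 2
        assert (out["temperature_max"] == 20.0).all()

    def test_daily_maxima_matches_scan_oracle(self):
        rng = np.random.default_rng(10)
        ts = pd.date_range("2020-06-01", periods=7 * 24, freq="h")
        s = pd.DataFrame(
            {
                "timestamp": ts,
                "temperature": rng.normal(30, 5, len(ts)),
                "humidity": rng.uniform(10, 90, len(ts)),
            }
        )
        out = cs.daily_maxima(s).set_index("date")
        for date, grp in s.groupby(pd.to_datetime(s["timestamp"]).dt.date):
            assert out.loc[date, "temperature_max"] == grp["temperature"].max()
            assert out.loc[date, "humidity_max"] == grp["humidity"].max()


class TestMannWhitney:
    def test_fully_separated_samples(self):
        res = cs.mann_whitney_u([1, 2], [3, 4])
        assert res.u == 0.0
        assert res.w == res.u + 2 * 3 / 2

    def test_identical_multisets_symmetric(self):
        x = [1.0, 2.0, 2.0, 5.0]
        res = cs.mann_whitney_u(x, list(x))
        assert res.u == len(x) * len(x) / 2

    def test_u_matches_brute_force_pair_count(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x = rng.integers(0, 10, size=int(rng.integers(2, 15))).astype(float)
            y = rng.integers(0, 10, size=int(rng.integers(2, 15))).astype(float)
            brute = sum(
                1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in x for yj in y
            )
            assert cs.mann_whitney_u(x, y).u == pytest.approx(brute)

    def test_u_and_p_match_scipy(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.8, 1, 25)
        ours = cs.mann_whitney_u(x, y, method="normal")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.u == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_normal_approximation_close_to_exact(self):
        # continuous (tie-free) samples, as for daily climate maxima
        rng = np.random.default_rng(13)
        for _ in range(50):
            x = rng.normal(0, 1, size=int(rng.integers(6, 11)))
            y = rng.normal(rng.uniform(-1, 1), 1, size=int(rng.integers(6, 9)))
            exact = cs.mann_whitney_u(x, y, method="exact").p
            approx = cs.mann_whitney_u(x, y, method="normal").p
            assert abs(exact - approx) <= 0.02

    def test_degenerate_identical_values(self):
        res = cs.mann_whitney_u([3, 3, 3], [3, 3])
        assert res.p == 1.0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            cs.mann_whitney_u([], [1.0])
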