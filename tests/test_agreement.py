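"""Repeatability and regression statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from octmorph.agreement import (PairedMeasurements, RegressionResult, bland_altman,
                                coefficient_of_variation, fit_regression, icc,
                                paired_test, select_model, spearman_rho)
from octmorph.core import (CollinearityError, ConstantInputError, DegenerateDataError)


def pairs_from(obs1, obs2):
    obs1 = np.asarray(obs1, dtype=float)
    return PairedMeasurements(np.arange(len(obs1)), obs1, np.asarray(obs2, float))


class TestPairedTest:
    def test_identical_sessions_degenerate_p_one(self):
        p, used = paired_test(pairs_from([1, 2, 3, 4], [1, 2, 3, 4]))
        assert p == 1.0 and used == "degenerate"

    def test_large_constant_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 1, 20)
        p, _ = paired_test(pairs_from(a, a + 5 + rng.normal(0, 0.1, 20)))
        assert p < 1e-3

    @pytest.mark.parametrize("null", ["gaussian", "skewed"])
    def test_type_one_error_within_binomial_band(self, null):
        """Rejection rate at alpha=0.05 under a true null stays inside the
        95% binomial band over 1,000 simulations."""
        rng = np.random.default_rng(7 if null == "gaussian" else 8)
        rejections = 0
        n_sim, n = 1000, 20
        for _ in range(n_sim):
            if null == "gaussian":
                a = rng.normal(10, 1, n)
                b = a + rng.normal(0, 0.5, n)
            else:  # skewed marginals, exchangeable sessions -> symmetric diffs
                subj = rng.normal(10, 1, n)
                a = subj + rng.exponential(0.5, n)
                b = subj + rng.exponential(0.5, n)
            p, _ = paired_test(pairs_from(a, b))
            rejections += p < 0.05
        band = 1.96 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rejections / n_sim - 0.05) < band + 0.01


class TestICC:
    def test_perfect_agreement_is_one(self):
        p = pairs_from([10, 11, 12, 13, 15], [10, 11, 12, 13, 15])
        val, _ = icc(p)
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_independent_sessions_near_zero(self):
        rng = np.random.default_rng(0)
        val, _ = icc(pairs_from(rng.normal(0, 1, 500), rng.normal(0, 1, 500)))
        assert abs(val) < 0.15

    def test_six_subject_longhand_anova_oracle(self):
        """Explicit longhand sums of squares reproduce ICC(A,1) to 1e-12."""
        data = np.array([[9.8, 10.1], [11.2, 11.5], [10.4, 10.2],
                         [12.1, 12.4], [9.5, 9.9], [10.9, 10.6]])
        n, k = data.shape
        grand = data.sum() / data.size
        ss_rows = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
        ss_cols = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
        ss_tot = sum((v - grand) ** 2 for v in data.ravel())
        msr = ss_rows / (n - 1)
        msc = ss_cols / (k - 1)
        mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        val, _ = icc(pairs_from(data[:, 0], data[:, 1]))
        assert val == pytest.approx(expected, abs=1e-12)

    @given(st.integers(5, 20), st.integers(0, 1000))
    def test_matches_pingouin_two_way_absolute_single(self, n, seed):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed)
        subj = rng.normal(10, 1, n)
        a = subj + rng.normal(0, 0.3, n)
        b = subj + rng.normal(0, 0.3, n)
        val, ci = icc(pairs_from(a, b))
        df = pd.DataFrame({
            "subject": np.r_[np.arange(n), np.arange(n)],
            "rater": ["A"] * n + ["B"] * n,
            "score": np.r_[a, b]})
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert val == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin rounds its CI to two decimals
        assert ci[0] == pytest.approx(row["CI95"][0], abs=6e-3)
        assert ci[1] == pytest.approx(row["CI95"][1], abs=6e-3)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        subj = rng.normal(10, 1, 40)
        a = subj + rng.normal(0, 0.2, 40)
        b = subj + rng.normal(0, 0.2, 40)
        v1, _ = icc(pairs_from(a, b))
        v2, _ = icc(pairs_from(3.7 * a, 3.7 * b))
        assert v2 == pytest.approx(v1, abs=1e-12)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(4)
        subj = rng.normal(10, 1, 25)
        a = subj + rng.normal(0, 0.2, 25)
        b = subj + rng.normal(0, 0.2, 25)
        perm = rng.permutation(25)
        v1, _ = icc(pairs_from(a, b))
        v2, _ = icc(pairs_from(a[perm], b[perm]))
        assert v2 == pytest.approx(v1, abs=1e-12)

    def test_zero_between_subject_variance_errors(self):
        with pytest.raises(DegenerateDataError):
            icc(pairs_from([5, 5, 5, 5], [5, 5, 5, 5]))


class TestCoV:
    def test_identical_sessions_zero(self):
        v, _ = coefficient_of_variation(pairs_from([8, 9, 10], [8, 9, 10]))
        assert v == 0.0

    def test_constant_difference_closed_form(self):
        d, m = 0.4, 10.0
        a = np.array([m - 1, m, m + 1]) + d / 2
        b = np.array([m - 1, m, m + 1]) - d / 2
        v, _ = coefficient_of_variation(pairs_from(a, b))
        assert v == pytest.approx(100 * (d / np.sqrt(2)) / m, abs=1e-9)

    def test_known_sigma_simulation(self):
        rng = np.random.default_rng(5)
        n, m, sw = 1000, 12.0, 0.3
        subj = rng.normal(m, 0.6, n)
        a = subj + rng.normal(0, sw, n)
        b = subj + rng.normal(0, sw, n)
        v, ci = coefficient_of_variation(pairs_from(a, b), seed=1)
        target = 100 * sw / m
        se = target / np.sqrt(2 * n)  # chi-based SE of an RMS estimate
        assert abs(v - target) < 3 * se + 0.05
        assert ci[0] < v < ci[1]

    def test_bootstrap_is_seeded(self):
        rng = np.random.default_rng(6)
        p = pairs_from(rng.normal(10, 1, 30), rng.normal(10, 1, 30))
        assert coefficient_of_variation(p, seed=2) == coefficient_of_variation(p, seed=2)


class TestBlandAltman:
    def test_constant_difference_collapses_limits(self):
        a = np.array([10.0, 11.0, 12.0])
        md, ci, (lo, hi) = bland_altman(pairs_from(a + 0.3, a))
        assert md == pytest.approx(0.3, abs=1e-12)
        assert lo == pytest.approx(hi) == pytest.approx(0.3)

    def test_swapping_sessions_negates_locations(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(10, 1, 20), rng.normal(10, 1, 20)
        md1, ci1, loa1 = bland_altman(pairs_from(a, b))
        md2, ci2, loa2 = bland_altman(pairs_from(b, a))
        assert md2 == pytest.approx(-md1, abs=1e-12)
        assert loa2[0] == pytest.approx(-loa1[1], abs=1e-12)
        assert (loa1[1] - loa1[0]) == pytest.approx(loa2[1] - loa2[0], abs=1e-12)

    def test_loa_width_tracks_difference_sd(self):
        """At the repeatability-table scale (sigma_d = 0.17, n = 20) the
        limits-of-agreement width lands near 2 * 1.96 * sigma_d."""
        rng = np.random.default_rng(10)
        widths = []
        for _ in range(300):
            a = rng.normal(13, 0.6, 20)
            b = a - rng.normal(0.02, 0.17, 20)
            _, _, (lo, hi) = bland_altman(pairs_from(a, b))
            widths.append(hi - lo)
        target = 2 * 1.96 * 0.17
        se = np.std(widths) / np.sqrt(len(widths))
        assert abs(np.mean(widths) - target) < 3 * se + 0.01


class TestSpearman:
    def test_monotone_transform_is_one(self):
        x = np.array([1.0, 2.5, 3.0, 7.0, 11.0])
        rho, _ = spearman_rho(x, np.exp(x / 4))
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_reversal_is_minus_one(self):
        x = np.arange(8, dtype=float)
        rho, _ = spearman_rho(x, x[::-1])
        assert rho == pytest.approx(-1.0, abs=1e-12)

    def test_constant_input_errors(self):
        with pytest.raises(ConstantInputError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    @given(st.lists(st.integers(0, 4), min_size=4, max_size=8),
           st.lists(st.integers(0, 4), min_size=4, max_size=8))
    def test_matches_midrank_enumeration_oracle(self, xs, ys):
        n = min(len(xs), len(ys))
        x = np.array(xs[:n], dtype=float)
        y = np.array(ys[:n], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return

        def midranks(v):
            return np.array([1 + np.sum(v < vi) + (np.sum(v == vi) - 1) / 2
                             for vi in v])

        rx, ry = midranks(x), midranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)


class TestRegression:
    def test_exact_linear_data(self):
        x = np.linspace(0, 10, 30)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1})
        res = fit_regression(df, "y", ["x"])
        assert res.coefficients["x"] == pytest.approx(2.0, abs=1e-10)
        assert res.coefficients["const"] == pytest.approx(1.0, abs=1e-9)
        assert res.adjusted_r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n, p = 40, 3
            X = rng.normal(0, 1, (n, p))
            y = X @ rng.normal(0, 2, p) + rng.normal(0, 1, n)
            df = pd.DataFrame(X, columns=["a", "b", "c"])
            df["y"] = y
            res = fit_regression(df, "y", ["a", "b", "c"])
            Xc = np.column_stack([np.ones(n), X])
            beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
            assert res.coefficients["const"] == pytest.approx(beta[0], abs=1e-9)
            for j, name in enumerate(["a", "b", "c"]):
                assert res.coefficients[name] == pytest.approx(beta[j + 1], abs=1e-9)

    def test_collinear_design_names_offenders(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"a": rng.normal(0, 1, 30)})
        df["b"] = 2 * df["a"]
        df["y"] = df["a"] + rng.normal(0, 1, 30)
        with pytest.raises(CollinearityError) as err:
            fit_regression(df, "y", ["a", "b"])
        assert set(err.value.columns) >= {"a", "b"}

    def test_pure_noise_predictor_lowers_adjusted_r2_in_expectation(self):
        """R² never decreases when adding a predictor; adjusted R² decreases
        in the majority of pure-noise additions (sign test p < 0.01)."""
        rng = np.random.default_rng(13)
        drops = 0
        n_sim = 200
        for _ in range(n_sim):
            n = 60
            x = rng.normal(0, 1, n)
            df = pd.DataFrame({"x": x, "z": rng.normal(0, 1, n),
                               "y": x + rng.normal(0, 1, n)})
            base = fit_regression(df, "y", ["x"])
            full = fit_regression(df, "y", ["x", "z"])
            assert full.r2 >= base.r2 - 1e-12
            drops += full.adjusted_r2 <= base.adjusted_r2
        assert stats.binomtest(drops, n_sim, 0.5, alternative="greater").pvalue < 0.01

    def test_slope_ci_coverage(self):
        """The 95% CI of the trephine-link slope covers the generating value
        in at least 93% of replicates."""
        rng = np.random.default_rng(14)
        beta, hits, n_sim = 1.07, 0, 300
        for _ in range(n_sim):
            t = rng.choice(np.arange(7.0, 9.51, 0.25), 109)
            y = 0.1 + beta * t + rng.normal(0, 0.43, 109)
            df = pd.DataFrame({"t": t, "y": y})
            lo, hi = fit_regression(df, "y", ["t"]).conf_int["t"]
            hits += lo <= beta <= hi
        assert hits / n_sim >= 0.93


class TestSelectModel:
    def _simulate(self, rng, n=500, betas=(1.0, 0.8, 0.6), n_noise=3, sigma=1.0):
        cols = {}
        for j in range(len(betas) + n_noise):
            cols[f"x{j}"] = rng.normal(0, 1, n)
        df = pd.DataFrame(cols)
        y = sum(b * df[f"x{j}"] for j, b in enumerate(betas))
        df["y"] = y + rng.normal(0, sigma, n)
        return df, [f"x{j}" for j in range(len(betas))]

    def test_single_candidate_equals_plain_fit(self):
        rng = np.random.default_rng(15)
        df, _ = self._simulate(rng, n=120, betas=(1.0,), n_noise=0)
        sel = select_model(df, "y", ["x0"])
        ref = fit_regression(df, "y", ["x0"])
        assert sel.predictors == ref.predictors
        assert sel.coefficients == ref.coefficients

    def test_strong_signal_never_misses_true_predictors(self):
        rng = np.random.default_rng(16)
        misses = 0
        for _ in range(60):
            df, truth = self._simulate(rng)
            sel = select_model(df, "y", list(df.columns.drop("y")))
            misses += not set(truth) <= set(sel.predictors)
        assert misses == 0

    def test_exact_recovery_rate_near_null_entry_probability(self):
        """With k pure-noise candidates the exact-truth selection rate sits
        near (1 - alpha)^k, the probability no null candidate enters."""
        rng = np.random.default_rng(17)
        exact = 0
        n_sim, k = 150, 3
        for _ in range(n_sim):
            df, truth = self._simulate(rng, n_noise=k)
            sel = select_model(df, "y", list(df.columns.drop("y")))
            exact += set(sel.predictors) == set(truth)
        rate = exact / n_sim
        expected = 0.95 ** k
        assert abs(rate - expected) < 3 * np.sqrt(expected * (1 - expected) / n_sim) + 0.03

    def test_all_noise_candidates_selects_at_most_one_mostly(self):
        rng = np.random.default_rng(18)
        small = 0
        n_sim = 100
        for _ in range(n_sim):
            df, _ = self._simulate(rng, betas=(), n_noise=5, sigma=1.0)
            df["y"] = rng.normal(0, 1, len(df))
            sel = select_model(df, "y", list(df.columns.drop("y")))
            small += len(sel.predictors) <= 1
        assert small / n_sim >= 0.90

    def test_selection_path_is_recorded(self):
        rng = np.random.default_rng(19)
        df, truth = self._simulate(rng)
        sel = select_model(df, "y", list(df.columns.drop("y")))
        added = [c for op, c, _ in sel.selection_path if op == "forward_add"]
        assert set(truth) <= set(added)
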