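"""Statistical stage: Spearman, FDR, descriptives, adjusted models.

Independent oracles: a brute-force rank computation for Spearman, a
hand-executed Benjamini-Hochberg step-up on four p values, the direct
textbook chi-squared formula on a 2x2 table, and the equality of the
standardised simple regression slope with the Pearson correlation.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pvsretina.associations import (RetinaPVSAssociation, attach_fdr,
                                    describe_cohort, fdr_adjust,
                                    fit_adjusted_model, spearman_matrix)
from pvsretina.synthetic import CohortSimParams, generate_cohort


def _brute_force_spearman(x, y):
    """Explicit average-rank formula, independent of scipy."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v)
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2)))


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "y": np.exp(x)})
        cells = spearman_matrix(df, ["x", "y"], n_boot=200, seed=0, min_pairs=5)
        assert cells[0].rho == pytest.approx(1.0, abs=1e-12)

    def test_toy_sample_matches_brute_force_ranks(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0, 2.0, 8.0]
        df = pd.DataFrame({"x": x, "y": y})
        cells = spearman_matrix(df, ["x", "y"], n_boot=200, seed=0, min_pairs=5)
        assert cells[0].rho == pytest.approx(_brute_force_spearman(x, y), abs=1e-12)
        assert cells[0].rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_ci_contains_point_estimate_and_pairwise_complete(self, rng):
        n = 60
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        y[:5] = np.nan  # forces the pairwise-complete path
        df = pd.DataFrame({"x": x, "y": y})
        cells = spearman_matrix(df, ["x", "y"], n_boot=300, seed=1)
        c = cells[0]
        assert c.n == n - 5
        assert c.ci_low <= c.rho <= c.ci_high

    def test_constant_variable_flagged_undefined(self, rng):
        df = pd.DataFrame({"x": np.ones(30), "y": rng.normal(size=30)})
        cells = spearman_matrix(df, ["x", "y"], n_boot=200, seed=0)
        assert np.isnan(cells[0].rho)

    def test_too_few_pairs_reported(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=5), "y": rng.normal(size=5)})
        with pytest.raises(ValueError, match="pairs"):
            spearman_matrix(df, ["x", "y"], n_boot=200, seed=0)

    def test_deterministic_given_seed(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=40), "y": rng.normal(size=40)})
        a = spearman_matrix(df, ["x", "y"], n_boot=250, seed=5)[0]
        b = spearman_matrix(df, ["x", "y"], n_boot=250, seed=5)[0]
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


class TestFDR:
    def test_hand_executed_step_up(self):
        """p = (0.01, 0.02, 0.03, 0.5), level 0.05: thresholds i/m*q are
        (0.0125, 0.025, 0.0375, 0.05); the largest i with p_(i) below its
        threshold is 3, so the first three are rejected. q values are the
        running minima of p_(i)*m/i from the top: (0.04, 0.04, 0.04, 0.5)."""
        q, rej = fdr_adjust([0.01, 0.02, 0.03, 0.5], level=0.05)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5], atol=1e-12)
        assert rej.tolist() == [True, True, True, False]

    def test_all_ones(self):
        q, rej = fdr_adjust([1.0, 1.0, 1.0])
        assert (q == 1.0).all() and not rej.any()

    def test_single_p_is_its_own_q(self):
        q, _ = fdr_adjust([0.037])
        assert q[0] == pytest.approx(0.037)

    def test_q_monotone_in_p_and_at_least_p(self, rng):
        p = rng.uniform(size=50)
        q, _ = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_rejections_shrink_as_level_decreases(self, rng):
        p = rng.uniform(size=40) ** 2
        _, r1 = fdr_adjust(p, level=0.10)
        _, r2 = fdr_adjust(p, level=0.01)
        assert set(np.flatnonzero(r2)) <= set(np.flatnonzero(r1))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestDescriptives:
    @staticmethod
    def _table(rng, n=40, shift=0.0):
        half = n // 2
        return pd.DataFrame({
            "included": [1] * half + [0] * half,
            "age": np.r_[rng.normal(72, 1, half), rng.normal(72 + shift, 1, half)],
            "sex": rng.integers(0, 2, n),
            "hypertension": rng.integers(0, 2, n),
            "diabetes": rng.integers(0, 2, n),
            "hypercholesterolemia": rng.integers(0, 2, n),
            "cvd": rng.integers(0, 2, n),
            "smoking": rng.integers(0, 2, n),
            "stroke": rng.integers(0, 2, n),
        })

    def test_chi_squared_matches_textbook_formula(self, rng):
        """2x2 counts (165, 216; 260, 225): chi2 = N (ad - bc)^2 /
        ((a+b)(c+d)(a+c)(b+d)), no continuity correction."""
        a, b, c, d = 165, 216, 260, 225
        n = a + b + c + d
        want = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        got = stats.chi2_contingency(np.array([[a, b], [c, d]]),
                                     correction=False).statistic
        assert got == pytest.approx(want, rel=1e-12)
        # and the wrapper reports the same p for equivalent group data
        tab = pd.DataFrame({
            "included": [1] * (a + b) + [0] * (c + d),
            "hypertension": [1] * a + [0] * b + [1] * c + [0] * d,
        })
        for col in ["age", "sex", "diabetes", "hypercholesterolemia", "cvd",
                    "smoking", "stroke"]:
            tab[col] = 0
        out = describe_cohort(tab, continuous_vars=[], binary_vars=["hypertension"])
        assert out.loc[0, "p_value"] == pytest.approx(stats.chi2.sf(want, 1), rel=1e-9)

    def test_identical_groups_give_t_zero_p_one(self, rng):
        base = self._table(rng)
        mirrored = pd.concat([base[base.included == 1],
                              base[base.included == 1].assign(included=0)])
        out = describe_cohort(mirrored, continuous_vars=["age"], binary_vars=[])
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_zero_variance_test_skipped_with_note(self, rng):
        t = self._table(rng)
        t["age"] = 72.0
        out = describe_cohort(t, continuous_vars=["age"], binary_vars=[])
        assert np.isnan(out.loc[0, "p_value"])
        assert "skipped" in out.loc[0, "note"]

    def test_welch_detects_mean_shift(self, rng):
        out = describe_cohort(self._table(rng, n=400, shift=0.5),
                              continuous_vars=["age"], binary_vars=[])
        assert out.loc[0, "p_value"] < 0.01

    def test_missing_split_column_reported(self, rng):
        with pytest.raises(ValueError, match="included"):
            describe_cohort(self._table(rng).drop(columns=["included"]))


class TestAdjustedModels:
    def test_standardised_simple_regression_equals_pearson(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        df = pd.DataFrame({"y": y, "x": x})
        res = fit_adjusted_model(df, "y", "x", covariates=[])
        assert res.beta == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-10)

    def test_standardised_identity_holds(self, rng):
        df = generate_cohort(CohortSimParams(n_subjects=381, seed=1))
        res = fit_adjusted_model(df, "pvs_total_volume", "left_crae")
        ratio = df["left_crae"].std() / df["pvs_total_volume"].std()
        assert res.beta == pytest.approx(res.b * ratio, rel=1e-8)

    def test_duplicate_predictor_reported(self, rng):
        df = generate_cohort(CohortSimParams(n_subjects=381, seed=1))
        with pytest.raises(ValueError, match="duplicated"):
            fit_adjusted_model(df, "pvs_total_volume", "left_crae",
                               covariates=["left_crae", "age"])

    def test_perfectly_collinear_covariate_named(self, rng):
        df = generate_cohort(CohortSimParams(n_subjects=381, seed=1))
        df["crae_copy"] = df["left_crae"]
        with pytest.raises(ValueError, match="crae_copy"):
            fit_adjusted_model(df, "pvs_total_volume", "left_crae",
                               covariates=["crae_copy", "age"])

    def test_too_few_cases_reported(self, rng):
        df = generate_cohort(CohortSimParams(n_subjects=30, seed=1))
        with pytest.raises(ValueError, match="complete cases"):
            fit_adjusted_model(df, "pvs_total_volume", "left_crae")

    def test_complete_case_rows_counted(self, rng):
        df = generate_cohort(CohortSimParams(n_subjects=381, seed=2))
        df.loc[:20, "left_crae"] = np.nan
        res = fit_adjusted_model(df, "pvs_total_volume", "left_crae")
        assert res.n == 381 - 21


class TestModelSurface:
    def test_fit_produces_cells_models_and_summary(self):
        df = generate_cohort(CohortSimParams(n_subjects=381, seed=4))
        model = RetinaPVSAssociation(df, brain_vars=["pvs_count"],
                                     retinal_vars=["left_crae", "left_fda"])
        model.params.n_boot = 300
        res = model.fit(seed=1)
        assert len(res.cells) == 3  # C(3, 2) pairs
        assert len(res.models) == 2
        cell = res.get_cell("pvs_count", "left_crae")
        assert -1 <= cell.rho <= 1 and cell.q_value >= cell.p_value - 1e-12
        text = res.summary()
        assert "pvs_count" in text and "left_crae" in text
        mat = res.correlation_matrix()
        assert np.allclose(np.diag(mat), 1.0)
        assert mat.loc["pvs_count", "left_crae"] == mat.loc["left_crae", "pvs_count"]

    def test_fdr_family_is_whole_matrix(self):
        df = generate_cohort(CohortSimParams(n_subjects=381, seed=4))
        model = RetinaPVSAssociation(df, brain_vars=["pvs_count", "pvs_mean_size"],
                                     retinal_vars=["left_crae", "right_crae"])
        model.params.n_boot = 300
        res = model.fit(seed=0)
        finite = [c for c in res.cells if np.isfinite(c.p_value)]
        # recomputing BH over all cells jointly reproduces the q values
        q, _ = fdr_adjust([c.p_value for c in finite])
        np.testing.assert_allclose([c.q_value for c in finite], q, atol=1e-12)
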