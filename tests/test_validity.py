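"""Convergent/discriminant validity statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from phenomarker.validity import (build_report, cutoff_proportions,
                                  dependent_corr_z, impute_and_pool,
                                  partial_corr, pearson_ci)


class TestPearsonCI:
    # printed r values with their published upper 95% bounds at n=59
    @pytest.mark.parametrize("r,upper", [
        (0.702, 0.812), (0.357, 0.562), (0.384, 0.583), (-0.138, 0.122),
    ])
    def test_reproduces_published_upper_bounds(self, r, upper):
        assert pearson_ci(r, 59)[1] == pytest.approx(upper, abs=5e-4)

    def test_zero_r_symmetric(self):
        lo, hi = pearson_ci(0.0, 30)
        assert lo == -hi

    def test_monotone_in_r(self):
        uppers = [pearson_ci(r, 59)[1] for r in np.linspace(-0.9, 0.9, 19)]
        assert all(np.diff(uppers) > 0)

    def test_narrows_with_n(self):
        widths = [np.diff(pearson_ci(0.5, n))[0] for n in (10, 50, 200, 1000)]
        assert all(np.diff(widths) < 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_ci(1.0, 59)
        with pytest.raises(ValueError):
            pearson_ci(0.5, 3)


class TestDependentCorrZ:
    def test_equal_correlations_give_zero(self):
        z, p = dependent_corr_z(0.5, 0.5, 0.3, 59)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_matches_independent_formula(self):
        # independent re-derivation of the pooled Steiger statistic
        r_jk, r_jh, r_kh, n = 0.7, 0.3, 0.4, 59
        rbar = (r_jk + r_jh) / 2
        cov = (r_kh * (1 - 2 * rbar ** 2)
               - 0.5 * rbar ** 2 * (1 - 2 * rbar ** 2 - r_kh ** 2))
        cbar = cov / (1 - rbar ** 2) ** 2
        expect = ((math.atanh(r_jk) - math.atanh(r_jh))
                  * math.sqrt((n - 3) / (2 - 2 * cbar)))
        z, _ = dependent_corr_z(r_jk, r_jh, r_kh, n)
        assert z == pytest.approx(expect, abs=1e-12)
        assert z == pytest.approx(3.4784, abs=1e-3)  # frozen from the formula

    def test_antisymmetry(self):
        z1, _ = dependent_corr_z(0.6, 0.2, 0.5, 59)
        z2, _ = dependent_corr_z(0.2, 0.6, 0.5, 59)
        assert z1 == pytest.approx(-z2)

    def test_magnitude_grows_with_n(self):
        zs = [abs(dependent_corr_z(0.7, 0.3, 0.4, n)[0])
              for n in (20, 59, 200, 1000)]
        assert all(np.diff(zs) > 0)

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            dependent_corr_z(0.9, -0.9, 0.9, 59)


class TestPartialCorr:
    def test_unrelated_controls_leave_r_unchanged(self, rng):
        n = 1000
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        c = rng.normal(size=(n, 2))
        r_raw = np.corrcoef(x, y)[0, 1]
        r_part, _ = partial_corr(x, y, c)
        assert r_part == pytest.approx(r_raw, abs=0.03)

    def test_variable_equal_to_control_fully_adjusted(self, rng):
        n = 50
        c = rng.normal(size=n)
        x = rng.normal(size=n)
        r, _ = partial_corr(x, c, c)
        assert r == 0.0

    def test_matches_first_order_closed_form(self, rng):
        n = 4000
        c = rng.normal(size=n)
        x = 0.5 * c + rng.normal(size=n)
        y = 0.7 * c + 0.3 * x + rng.normal(size=n)
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xc = np.corrcoef(x, c)[0, 1]
        r_yc = np.corrcoef(y, c)[0, 1]
        closed = (r_xy - r_xc * r_yc) / math.sqrt((1 - r_xc ** 2)
                                                  * (1 - r_yc ** 2))
        r, _ = partial_corr(x, y, c)
        assert r == pytest.approx(closed, abs=1e-10)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 200
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("xyab"))
        df["y"] += 0.5 * df["x"] + 0.3 * df["a"]
        expected = float(pingouin.partial_corr(df, x="x", y="y",
                                               covar=["a", "b"])["r"].iloc[0])
        r, _ = partial_corr(df["x"], df["y"], df[["a", "b"]])
        assert r == pytest.approx(expected, abs=1e-8)

    def test_collinear_controls_rejected(self, rng):
        n = 40
        c = rng.normal(size=n)
        with pytest.raises(ValueError, match="collinear"):
            partial_corr(rng.normal(size=n), rng.normal(size=n),
                         np.column_stack([c, 2 * c]))


class TestImputeAndPool:
    def _table(self, n=500, rho=0.5, seed=0):
        r = np.random.default_rng(seed)
        x = r.normal(size=n)
        y = rho * x + math.sqrt(1 - rho ** 2) * r.normal(size=n)
        return pd.DataFrame({"x": x, "y": y, "z": r.normal(size=n)})

    def test_no_missing_reduces_to_complete_data(self):
        t = self._table()
        out = impute_and_pool(t, [("x", "y")], m=7, seed=1)
        complete = np.corrcoef(t["x"], t["y"])[0, 1]
        assert out["r"].iloc[0] == pytest.approx(complete, abs=1e-12)

    def test_mcar_holes_recover_complete_data_estimate(self):
        diffs = []
        for seed in range(10):
            t = self._table(seed=seed)
            complete = np.corrcoef(t["x"], t["y"])[0, 1]
            r = np.random.default_rng(1000 + seed)
            holes = t.copy()
            holes.loc[r.random(len(t)) < 0.14, "y"] = np.nan
            out = impute_and_pool(holes, [("x", "y")], m=10, seed=seed)
            diffs.append(out["r"].iloc[0] - complete)
        assert np.all(np.abs(diffs) < 0.08)

    def test_stable_in_number_of_imputations(self):
        t = self._table(seed=3)
        r = np.random.default_rng(5)
        t.loc[r.random(len(t)) < 0.14, "y"] = np.nan
        r5 = impute_and_pool(t, [("x", "y")], m=5, seed=2)["r"].iloc[0]
        r50 = impute_and_pool(t, [("x", "y")], m=50, seed=2)["r"].iloc[0]
        assert abs(r5 - r50) < 0.02

    def test_fully_missing_column_rejected(self):
        t = self._table(n=30)
        t["y"] = np.nan
        with pytest.raises(ValueError, match="entirely MISSING"):
            impute_and_pool(t, [("x", "y")], m=5, seed=0)

    def test_deterministic_given_seed(self):
        t = self._table(seed=4)
        t.iloc[::7, 1] = np.nan
        a = impute_and_pool(t, [("x", "y")], m=5, seed=9)
        b = impute_and_pool(t, [("x", "y")], m=5, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestCutoffProportions:
    @pytest.mark.parametrize("scores,expect", [
        ([33, 34, 35], (2 / 3, 0.0)),
        ([0, 0, 0], (0.0, 0.0)),
        ([36, 36, 10, 50], (0.75, 0.75)),
    ])
    def test_hand_counts(self, scores, expect):
        assert cutoff_proportions(scores) == pytest.approx(expect)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cutoff_proportions([10, 90])


class TestBuildReport:
    def _surveys(self, n=59, seed=0):
        r = np.random.default_rng(seed)
        sias = np.clip(np.round(r.normal(29, 9, n)), 0, 80)
        df = pd.DataFrame({
            "sias": sias,
            "dass_dep": np.clip(np.round(5 + 0.2 * sias
                                         + r.normal(0, 3, n)), 0, 21),
            "panas_na": np.clip(np.round(15 + 0.3 * sias
                                         + r.normal(0, 5, n)), 10, 50),
            "panas_pa": np.clip(np.round(35 - 0.1 * sias
                                         + r.normal(0, 5, n)), 10, 50),
        }, index=[f"p{i:03d}" for i in range(n)])
        return df

    def test_perfect_predictions(self):
        surveys = self._surveys()
        preds = pd.Series(surveys["sias"].to_numpy(float),
                          index=surveys.index)
        rep = build_report(preds, surveys, m_imputations=3, seed=0)
        assert rep.r_convergent == pytest.approx(1.0)
        assert rep.ci_convergent[0] <= rep.r_convergent <= rep.ci_convergent[1]

    def test_shuffled_predictions_near_null(self):
        surveys = self._surveys()
        rs, zs = [], []
        for seed in range(8):
            r = np.random.default_rng(seed)
            preds = pd.Series(r.permutation(surveys["sias"].to_numpy(float)),
                              index=surveys.index)
            rep = build_report(preds, surveys, m_imputations=3, seed=seed)
            rs.append(rep.r_convergent)
            zs.append(rep.z_dep)
        assert abs(np.mean(rs)) < 0.15
        assert abs(np.mean(zs)) < 1.0

    def test_in_sample_predictions_refused(self):
        surveys = self._surveys()
        preds = pd.Series(surveys["sias"].to_numpy(float), index=surveys.index)
        with pytest.raises(ValueError, match="out-of-sample"):
            build_report(preds, surveys, out_of_sample=False)

    def test_report_fields_coherent(self):
        surveys = self._surveys(seed=2)
        r = np.random.default_rng(3)
        noisy = surveys["sias"].to_numpy(float) + r.normal(0, 6, len(surveys))
        rep = build_report(pd.Series(noisy, index=surveys.index),
                           surveys, m_imputations=5, seed=1)
        for lo, point, hi in [
            (rep.ci_convergent[0], rep.r_convergent, rep.ci_convergent[1]),
            (rep.ci_dep[0], rep.r_dep, rep.ci_dep[1]),
            (rep.ci_partial[0], rep.r_partial, rep.ci_partial[1]),
        ]:
            assert lo <= point <= hi
        assert abs(rep.r_convergent) <= 1
        assert 0 <= rep.pct_above_34 <= 1
        assert rep.n_effective == 59
        d = rep.to_dict()
        assert set(d) >= {"r_convergent", "z_dep", "pct_above_36"}
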