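"""OLS fitting, BIC ranking, screening, VIF and semivariogram diagnostics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from moosehab.regression import (ModelSpec, best_subsets, bic, fit_ols,
                                 predict_residuals, residual_semivariogram,
                                 screen_collinearity, vif)


def _toy(n=40, seed=3, p=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    cols = {f"x{i+1}": X[:, i] for i in range(p)}
    y = 1.0 + 2.0 * X[:, 0] - 1.5 * X[:, 1] + rng.normal(0, 0.5, n)
    return pd.DataFrame({"y": y, **cols})


class TestFitOls:
    def test_exact_linear_relation(self):
        t = pd.DataFrame({"x1": [0.0, 1, 2, 3, 4]})
        t["y"] = 3.0 - 2.0 * t["x1"]
        fit = fit_ols(t, ModelSpec("y", ("x1",)))
        assert fit.r2 == pytest.approx(1.0)
        assert fit.r2_adj == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equations_on_five_points(self):
        t = pd.DataFrame({"x1": [0.0, 1, 2, 3, 4], "x2": [1.0, 0, 2, 1, 3],
                          "y": [1.2, 0.7, 2.9, 2.1, 4.4]})
        fit = fit_ols(t, ModelSpec("y", ("x1", "x2")))
        X = np.column_stack([np.ones(5), t["x1"], t["x2"]])
        beta = np.linalg.solve(X.T @ X, X.T @ t["y"].to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=1e-10)
        resid = t["y"].to_numpy() - X @ beta
        assert fit.rss == pytest.approx(resid @ resid)
        assert fit.rmse == pytest.approx(math.sqrt(resid @ resid / 5))

    def test_row_permutation_invariance(self, rng):
        t = _toy()
        fit1 = fit_ols(t, ModelSpec("y", ("x1", "x2")))
        fit2 = fit_ols(t.sample(frac=1, random_state=5), ModelSpec("y", ("x1", "x2")))
        np.testing.assert_allclose(fit1.params, fit2.params)
        assert fit1.bic == pytest.approx(fit2.bic)

    def test_rank_deficiency_names_columns(self):
        t = _toy()
        t["dup"] = t["x1"]
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(t, ModelSpec("y", ("x1", "x2", "dup")))

    def test_r2_adj_penalises_noise_predictor(self):
        t = _toy(n=30)
        base = fit_ols(t, ModelSpec("y", ("x1", "x2")))
        noisy = fit_ols(t, ModelSpec("y", ("x1", "x2", "x3")))
        assert noisy.r2 >= base.r2
        # x3 is pure noise: the adjusted R2 should not improve as much as R2
        assert noisy.r2_adj - base.r2_adj < noisy.r2 - base.r2


class TestBic:
    def test_extra_predictor_with_same_rss_costs_ln_n(self):
        n, rss = 62, 4.2
        assert bic(rss=rss, n=n, p=4) - bic(rss=rss, n=n, p=3) == pytest.approx(math.log(n))

    def test_delta_invariant_to_shared_constant(self):
        # rescaling the response scales RSS by c^2 in both models: the n*ln
        # term shifts both BICs by the same constant and the difference holds
        a1, a2 = bic(rss=3.0, n=50, p=2), bic(rss=5.0, n=50, p=4)
        c = 7.3
        b1, b2 = bic(rss=3.0 * c, n=50, p=2), bic(rss=5.0 * c, n=50, p=4)
        assert (a2 - a1) == pytest.approx(b2 - b1)

    def test_exact_fit_flagged_minus_infinity(self):
        assert bic(rss=0.0, n=10, p=1) == -math.inf


def enumerate_oracle(table, response, candidates, max_size):
    """Independent brute force: numpy lstsq per subset + explicit BIC."""
    y = table[response].to_numpy()
    n = len(y)
    out = []
    for size in range(max_size + 1):
        for combo in itertools.combinations(candidates, size):
            X = np.column_stack([np.ones(n)] + [table[c].to_numpy() for c in combo])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            b = -math.inf if rss <= 1e-20 else n * math.log(rss / n) + (size + 1) * math.log(n)
            out.append((combo, b))
    out.sort(key=lambda t: (t[1], len(t[0]), t[0]))
    return out


class TestBestSubsets:
    def test_two_candidates_enumerate_four_models(self):
        t = _toy(p=2)
        res = best_subsets(t, "y", ["x1", "x2"])
        assert len(res.models) == 4

    def test_noiseless_response_selects_generating_predictor(self):
        t = _toy(p=3)
        t["y"] = 2.0 + 3.0 * t["x1"]
        res = best_subsets(t, "y", ["x1", "x2", "x3"])
        assert res.best.spec.predictors == ("x1",)
        assert res.best.delta_bic == 0.0

    def test_ranking_matches_independent_enumeration(self):
        t = _toy(n=60, seed=9, p=8)
        t["y"] = 1 + 1.2 * t["x1"] - 0.8 * t["x5"] + np.random.default_rng(2).normal(0, 1, 60)
        cands = [f"x{i+1}" for i in range(8)]
        res = best_subsets(t, "y", cands, max_size=4)
        oracle = enumerate_oracle(t, "y", cands, 4)
        assert len(res.models) == len(oracle)
        for model, (combo, b) in zip(res.models, oracle):
            assert model.spec.predictors == combo
            assert model.fit.bic == pytest.approx(b, rel=1e-9)

    def test_missing_candidate_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            best_subsets(_toy(), "y", ["nope"])


class TestScreening:
    def test_proportional_columns_cluster_at_zero_distance(self):
        t = _toy(n=50)
        t["x2"] = 2.0 * t["x1"]
        rep = screen_collinearity(t, ["x1", "x2", "x3"], cluster_columns=["x1", "x2", "x3"])
        assert rep.pearson.loc["x1", "x2"] == pytest.approx(1.0)
        clusters = [set(m) for m in rep.clusters.values()]
        assert {"x1", "x2"} in clusters
        assert rep.retained == ["x1", "x3"]

    def test_independent_columns_not_pruned(self, rng):
        t = pd.DataFrame(rng.normal(size=(600, 5)), columns=list("abcde"))
        rep = screen_collinearity(t, list("abcde"), cluster_columns=list("abcde"))
        off = rep.pearson.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.2
        assert rep.retained == list("abcde")

    def test_constant_column_flagged(self):
        t = _toy()
        t["c"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            screen_collinearity(t, ["x1", "c"])


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        from scipy.linalg import hadamard
        H = hadamard(8).astype(float)
        t = pd.DataFrame(H[:, 1:4], columns=["x1", "x2", "x3"])
        v = vif(t, ["x1", "x2", "x3"])
        np.testing.assert_allclose(v, 1.0, atol=1e-12)

    def test_known_pairwise_correlation_formula(self):
        # exact sample correlation r = 0.89 between two predictors, as between
        # annual mean temperature and human footprint: VIF = 1/(1-r^2) ~ 4.81
        rng = np.random.default_rng(4)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        a = (a - a.mean()) / a.std()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal to a
        b /= b.std()
        r = 0.89
        t = pd.DataFrame({"p": a, "q": r * a + math.sqrt(1 - r**2) * b})
        v = vif(t, ["p", "q"])
        np.testing.assert_allclose(v, 1 / (1 - r**2), rtol=1e-9)
        assert v["p"] == pytest.approx(4.81, abs=0.01)

    def test_duplicated_column_infinite(self):
        t = _toy()
        t["dup"] = t["x1"]
        assert np.isinf(vif(t, ["x1", "dup"])["dup"])


class TestResiduals:
    def test_training_residuals_sum_to_zero(self):
        t = _toy()
        fit = fit_ols(t, ModelSpec("y", ("x1", "x2")))
        out = predict_residuals(fit, t)
        assert out["residual"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_perfect_fit_zero_residuals(self):
        t = pd.DataFrame({"x1": [0.0, 1, 2, 3]})
        t["y"] = 5 + t["x1"]
        fit = fit_ols(t, ModelSpec("y", ("x1",)))
        out = predict_residuals(fit, t)
        np.testing.assert_allclose(out["residual"], 0.0, atol=1e-12)

    def test_largest_residual_region_stable_under_permutation(self):
        t = _toy().assign(region_id=np.arange(40))
        fit = fit_ols(t, ModelSpec("y", ("x1",)))
        r1 = predict_residuals(fit, t)
        r2 = predict_residuals(fit, t.sample(frac=1, random_state=0))
        top1 = r1.loc[r1["residual"].idxmax(), "region_id"]
        top2 = r2.loc[r2["residual"].idxmax(), "region_id"]
        assert top1 == top2


class TestSemivariogram:
    def test_constant_residuals_zero_everywhere(self, rng):
        coords = rng.uniform(0, 10, size=(20, 2))
        sv = residual_semivariogram(np.full(20, 1.3), coords, n_bins=5)
        assert np.nanmax(sv.semivariance) == 0.0

    def test_two_points_definition(self):
        sv = residual_semivariogram(np.array([1.0, 3.0]), np.array([[0, 0], [1, 0.0]]), n_bins=1)
        assert sv.semivariance[0] == pytest.approx(2.0)  # (1-3)^2 / 2
        assert sv.pair_counts.sum() == 1

    def test_pair_counts_cover_all_pairs(self, rng):
        n = 30
        sv = residual_semivariogram(rng.normal(size=n), rng.uniform(0, 5, (n, 2)), n_bins=6)
        assert sv.pair_counts.sum() == n * (n - 1) // 2

    def test_iid_noise_shows_no_distance_trend(self, rng):
        n = 300
        z = rng.normal(size=n)
        sv = residual_semivariogram(z, rng.uniform(0, 100, (n, 2)), n_bins=8)
        ok = sv.pair_counts > 50
        # bins fluctuate around the variance; relative spread stays small
        assert np.nanstd(sv.semivariance[ok]) / np.nanmean(sv.semivariance[ok]) < 0.25

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            residual_semivariogram(np.array([1.0, 2.0]), np.zeros((2, 2)))

    def test_greatcircle_distances_in_km(self):
        coords = np.array([[30.0, 60.0], [30.0, 61.0]])  # 1 degree of latitude
        sv = residual_semivariogram(np.array([0.0, 1.0]), coords, n_bins=1, metric="greatcircle")
        assert sv.bin_mid[0] * 2 == pytest.approx(111.19, rel=0.01)
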