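"""Design matrices, OLS fitting, evaluation and the factor-count scan."""
import numpy as np
import pandas as pd
import pytest

from gxegrowth import (
    GenotypeMatrix,
    ModelSpec,
    build_design_matrix,
    evaluate,
    factor_count_scan,
    fit_model,
    fit_ols,
    predict,
)


def _toy(n_cultivars=30, n_loci=60, n_envs=8, seed=0):
    rng = np.random.default_rng(seed)
    vals = (rng.random((n_cultivars, n_loci)) < rng.uniform(0.2, 0.5, n_loci)).astype(int)
    vals[0, vals.sum(axis=0) == 0] = 1
    loci = pd.DataFrame(
        {"chrom": ["chr01"] * n_loci, "pos": (np.arange(n_loci) + 1) * 150_000},
        index=[f"chr01_{(j + 1) * 150_000}" for j in range(n_loci)],
    )
    G = GenotypeMatrix(vals, loci, [f"cv{i:02d}" for i in range(n_cultivars)])
    envf = pd.DataFrame(
        {
            "T0": rng.uniform(18, 28, n_envs),
            "T30": rng.uniform(16, 26, n_envs),
            "sowing_doy": rng.integers(150, 230, n_envs).astype(float),
            "latitude": rng.uniform(31, 39, n_envs),
        },
        index=[f"env{k}" for k in range(n_envs)],
    )
    samples = pd.DataFrame(
        [(c, e) for e in envf.index for c in G.cultivars],
        columns=["cultivar", "environment"],
    )
    return G, envf, samples, rng


E_FACTORS = ("T0", "T30", "sowing_doy", "latitude")


class TestDesignMatrix:
    def test_column_count_for_full_pattern(self):
        G, envf, samples, _ = _toy()
        spec = ModelSpec("K", "G+E+GxE", tuple(G.locus_ids[:50]), E_FACTORS)
        X, labels = build_design_matrix(spec, G, envf, samples)
        assert X.shape == (len(samples), 1 + 50 + 4 + 200)
        assert len(labels) == 255 and labels[0] == "intercept"

    def test_noncarrier_rows_have_zero_interactions(self):
        G, envf, samples, _ = _toy()
        g = tuple(G.locus_ids[:3])
        spec = ModelSpec("K", "G+E+GxE", g, E_FACTORS)
        X, labels = build_design_matrix(spec, G, envf, samples)
        for h, locus in enumerate(g):
            x_col = X[:, 1 + h]
            for k in range(len(E_FACTORS)):
                inter = X[:, 1 + 3 + 4 + h * 4 + k]
                assert (inter[x_col == 0] == 0).all()
                # carriers inherit the environmental factor value itself
                z = X[:, 1 + 3 + k]
                np.testing.assert_allclose(inter[x_col == 1], z[x_col == 1])

    def test_pattern_e_rows_identical_within_environment(self):
        G, envf, samples, _ = _toy()
        spec = ModelSpec("K", "E", e_factors=E_FACTORS)
        X, _ = build_design_matrix(spec, G, envf, samples)
        df = pd.DataFrame(X)
        df["env"] = samples["environment"].to_numpy()
        for _, sub in df.groupby("env"):
            assert (sub.nunique(axis=0).drop("env") == 1).all()

    def test_unknown_sample_named_in_error(self):
        G, envf, samples, _ = _toy()
        bad = pd.DataFrame({"cultivar": ["nope"], "environment": [envf.index[0]]})
        spec = ModelSpec("K", "G", g_factors=tuple(G.locus_ids[:2]))
        with pytest.raises(KeyError, match="nope"):
            build_design_matrix(spec, G, envf, bad)


class TestFitOls:
    def test_exact_recovery_of_planted_coefficients(self):
        G, envf, samples, rng = _toy(seed=3)
        g = tuple(G.locus_ids[:2])
        spec = ModelSpec("K", "G+E+GxE", g, E_FACTORS)
        X, labels = build_design_matrix(spec, G, envf, samples)
        truth = pd.Series(0.0, index=labels)
        truth["intercept"] = 40.0
        truth[g[0]], truth[g[1]] = 5.0, -3.0
        truth["T0"], truth["T30"], truth["sowing_doy"], truth["latitude"] = 0.8, 0.3, -0.1, 2.0
        truth[f"{g[0]}:T0"] = 0.7
        truth[f"{g[1]}:latitude"] = -0.4
        y = X @ truth.to_numpy()
        fit = fit_ols(X, y, labels, spec)
        np.testing.assert_allclose(fit.coef.to_numpy(), truth.to_numpy(), atol=1e-6)

    def test_constant_response_loads_only_intercept(self):
        G, envf, samples, _ = _toy()
        spec = ModelSpec("K", "G+E", tuple(G.locus_ids[:5]), E_FACTORS)
        X, labels = build_design_matrix(spec, G, envf, samples)
        fit = fit_ols(X, np.full(len(samples), 7.5), labels, spec)
        assert fit.intercept == pytest.approx(7.5, abs=1e-9)
        assert np.abs(fit.coef.drop("intercept").to_numpy()).max() < 1e-9

    def test_residuals_orthogonal_to_design(self):
        G, envf, samples, rng = _toy(seed=5)
        spec = ModelSpec("K", "G+E", tuple(G.locus_ids[:10]), E_FACTORS)
        X, labels = build_design_matrix(spec, G, envf, samples)
        y = rng.normal(100, 20, len(samples))
        fit = fit_ols(X, y, labels, spec)
        resid = y - X @ fit.coef.to_numpy()
        # normal equations: X^T r = 0 (scaled by column norms for comparability)
        proj = X.T @ resid / np.linalg.norm(X, axis=0)
        assert np.abs(proj).max() < 1e-8

    def test_empty_input_errors(self):
        spec = ModelSpec("K", "G", g_factors=("a",))
        with pytest.raises(ValueError):
            fit_ols(np.empty((0, 2)), np.empty(0), ["intercept", "a"], spec)


class TestEvaluate:
    def test_perfect_shifted_and_negated_predictions(self):
        obs = np.array([1.0, 3.0, 2.0, 5.0])
        assert evaluate(obs, obs).pearson_r == pytest.approx(1.0)
        assert evaluate(obs, obs).rmse == pytest.approx(0.0)
        shifted = evaluate(obs, obs + 5.0)
        assert shifted.pearson_r == pytest.approx(1.0)
        assert shifted.rmse == pytest.approx(5.0)
        assert evaluate(obs, -obs).pearson_r == pytest.approx(-1.0)

    def test_constant_vector_reports_nan_r_with_rmse(self):
        obs = np.array([2.0, 2.0, 2.0])
        with pytest.warns(UserWarning, match="constant"):
            res = evaluate(obs, np.array([1.0, 2.0, 3.0]))
        assert np.isnan(res.pearson_r)
        assert res.rmse == pytest.approx(np.sqrt(2 / 3))


class TestScanAndPredict:
    def _samples_with_y(self, G, envf, samples, rng, gxe=True):
        g = list(G.locus_ids[:6])
        y = 30.0 + 4.0 * G.values[:, 0][samples["cultivar"].str[2:].astype(int)]
        z = envf.loc[samples["environment"], "T0"].to_numpy()
        y = y + 0.6 * z + rng.normal(0, 1.0, len(samples))
        if gxe:
            x0 = G.values[:, 1][samples["cultivar"].str[2:].astype(int)]
            y = y + 0.5 * x0 * z
        out = samples.copy()
        out["value"] = y
        return out, g

    def test_nested_patterns_and_factor_count_monotonicity(self):
        G, envf, samples, rng = _toy(seed=9)
        train, g = self._samples_with_y(G, envf, samples, rng)
        scan = factor_count_scan(
            "K", G, envf, train, None, g, list(E_FACTORS), n_g_max=6
        )
        tr = scan[scan["split"] == "train"].set_index(["pattern", "n_g"])
        for n_g in range(1, 7):
            r_g = tr.loc[("G", n_g), "pearson_r"]
            r_ge = tr.loc[("G+E", n_g), "pearson_r"]
            r_full = tr.loc[("G+E+GxE", n_g), "pearson_r"]
            assert r_g <= r_ge + 1e-12 <= r_full + 2e-12  # nested in-sample fit
        for pattern in ("G", "G+E", "G+E+GxE"):
            rs = tr.loc[pattern, "pearson_r"].to_numpy()
            assert (np.diff(rs) >= -1e-12).all()  # non-decreasing in n_g
        e_rows = tr.loc["E", "pearson_r"].to_numpy()
        np.testing.assert_allclose(e_rows, e_rows[0])  # E ignores n_g

    def test_in_sample_r2_identity(self):
        G, envf, samples, rng = _toy(seed=13)
        train, g = self._samples_with_y(G, envf, samples, rng)
        spec = ModelSpec("K", "G+E", tuple(g), E_FACTORS)
        fit = fit_model(spec, G, envf, train)
        pred = predict(fit, G, envf, train)
        y = train["value"].to_numpy()
        r = evaluate(y, pred).pearson_r
        sst = ((y - y.mean()) ** 2).sum()
        assert r**2 == pytest.approx(1.0 - fit.sse / sst, abs=1e-10)

    def test_predict_consistency(self):
        G, envf, samples, rng = _toy(seed=17)
        train, g = self._samples_with_y(G, envf, samples, rng)
        spec = ModelSpec("K", "G+E+GxE", tuple(g), E_FACTORS)
        fit = fit_model(spec, G, envf, train)
        pred = predict(fit, G, envf, samples)
        # permuting sample order permutes predictions identically
        perm = rng.permutation(len(samples))
        pred_perm = predict(fit, G, envf, samples.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(pred_perm, pred[perm])
        # a duplicated environment row gives the same prediction
        dup = pd.concat([samples.iloc[[0]], samples.iloc[[0]]]).reset_index(drop=True)
        both = predict(fit, G, envf, dup)
        assert both[0] == both[1]

    def test_scan_truncates_with_warning(self):
        G, envf, samples, rng = _toy(seed=19)
        train, g = self._samples_with_y(G, envf, samples, rng)
        with pytest.warns(UserWarning, match="truncating"):
            scan = factor_count_scan(
                "K", G, envf, train, None, g[:3], list(E_FACTORS), n_g_max=10
            )
        assert scan["n_g"].max() == 3
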