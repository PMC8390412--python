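import numpy as np
import pandas as pd
import pytest

from rollscore import rolling, simulate, wlmm
from rollscore.exceptions import InputError


# ---------------------------------------------------------------------------
# independent dense-matrix oracles


def dense_gls(X, y, w, fam, family_var, slope_var, sigma2, age_z=None):
    """Brute-force GLS through full n x n covariance inversion."""
    n = len(y)
    V = sigma2 * np.diag(1.0 / w)
    for f in np.unique(fam):
        idx = np.flatnonzero(fam == f)
        V[np.ix_(idx, idx)] += family_var
        if slope_var:
            V[np.ix_(idx, idx)] += slope_var * np.outer(age_z[idx], age_z[idx])
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


def dense_reml_neg2(X, y, w, fam, gamma, age_z=None):
    """Profiled -2 restricted log-likelihood (up to a constant), dense path."""
    n, p = X.shape
    V0 = np.diag(1.0 / w)
    for f in np.unique(fam):
        idx = np.flatnonzero(fam == f)
        V0[np.ix_(idx, idx)] += gamma[0]
        if len(gamma) > 1:
            V0[np.ix_(idx, idx)] += gamma[1] * np.outer(age_z[idx], age_z[idx])
    Vi = np.linalg.inv(V0)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    rss = r @ Vi @ r
    return (
        (n - p) * np.log(rss / (n - p))
        + np.linalg.slogdet(V0)[1]
        + np.linalg.slogdet(XtVX)[1]
    )


def _standardized(df):
    return rolling.standardize(df)


@pytest.fixture(scope="module")
def fixture_20rows():
    cfg = simulate.SimConfig(
        n_families=10, family_size=(1, 1), measures_per_person=(2, 2),
        beta_age=0.3, family_var=0.0, resid_var=1.0,
    )
    df, _ = simulate.simulate_measures(cfg, seed=5)
    return _standardized(df)


class TestBuildDesign:
    def test_hand_fixture_matrix(self, tiny_table):
        df = _standardized(tiny_table)
        design = wlmm.build_design(df)
        # hand-built X: intercept, pgs, age_z, age_z^2, sex, array[a2], pc1..5
        age = tiny_table["age"].to_numpy(float)
        age_z = (age - age.mean()) / age.std()
        pgs = tiny_table["pgs"].to_numpy(float)
        pgs_z = (pgs - pgs.mean()) / pgs.std()
        expected = np.column_stack(
            [
                np.ones(6),
                pgs_z,
                age_z,
                age_z**2,
                tiny_table["sex"],
                (tiny_table["array"] == "a2").astype(float),
            ]
            + [df[f"pc{i}"] for i in range(1, 6)]
        )
        assert design.xnames[:6] == [
            "intercept", "pgs", "age_z", "age2_z", "sex", "array[a2]",
        ]
        np.testing.assert_allclose(design.X, expected, atol=1e-12)

    def test_two_arrays_one_dummy(self, tiny_table):
        design = wlmm.build_design(_standardized(tiny_table))
        assert sum(nm.startswith("array[") for nm in design.xnames) == 1

    def test_random_slope_flag(self, tiny_table):
        d0 = wlmm.build_design(_standardized(tiny_table), random_slope=False)
        d1 = wlmm.build_design(_standardized(tiny_table), random_slope=True)
        assert not d0.random_slope and d1.random_slope

    def test_missing_column_raises(self, tiny_table):
        with pytest.raises(InputError, match="missing model columns"):
            wlmm.build_design(tiny_table.drop(columns=["pgs"]))

    def test_collinear_raises(self, small_standardized):
        df, _ = small_standardized
        df = df.iloc[:100].copy()
        df["pc5"] = df["pc4"]
        with pytest.raises(InputError, match="collinear"):
            wlmm.build_design(df)

    def test_nan_raises(self, tiny_table):
        df = _standardized(tiny_table)
        df.loc[2, "pgs"] = np.nan
        with pytest.raises(InputError, match="missing values"):
            wlmm.build_design(df)


class TestFit:
    def test_ols_limit_normal_equations(self, fixture_20rows):
        """Unit weights, singleton families, variance ratio forced to 0."""
        design = wlmm.build_design(fixture_20rows)
        fit = wlmm.fit(design, weights=None, fixed_ratios=(0.0,))
        X, y = design.X, design.y
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)  # normal-equations oracle
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)

    def test_gls_oracle_fixed_components(self):
        """3 families, known variance components, closed-form dense GLS."""
        cfg = simulate.SimConfig(
            n_families=3, family_size=(3, 3), measures_per_person=(2, 2),
            family_var=0.3, resid_var=0.7,
        )
        df, _ = simulate.simulate_measures(cfg, seed=10)
        df = _standardized(df)
        design = wlmm.build_design(df)
        rng = np.random.default_rng(1)
        w = rng.uniform(0.2, 1.0, design.n_rows)
        family_var, sigma2 = 0.3, 0.7
        fit = wlmm.fit(design, weights=w, fixed_ratios=(family_var / sigma2,))
        beta_oracle = dense_gls(
            design.X, design.y, w, design.family_codes, family_var, 0.0, sigma2
        )
        np.testing.assert_allclose(fit.beta, beta_oracle, atol=1e-6)

    def test_gls_oracle_random_slope(self):
        cfg = simulate.SimConfig(
            n_families=4, family_size=(3, 3), measures_per_person=(2, 2),
            family_var=0.3, slope_var=0.1, resid_var=0.6,
        )
        df, _ = simulate.simulate_measures(cfg, seed=13)
        df = _standardized(df)
        design = wlmm.build_design(df, random_slope=True)
        w = np.random.default_rng(2).uniform(0.3, 1.0, design.n_rows)
        fit = wlmm.fit(design, weights=w, fixed_ratios=(0.5, 0.2))
        beta_oracle = dense_gls(
            design.X, design.y, w, design.family_codes,
            0.5, 0.2, 1.0, age_z=design.age_z,
        )
        np.testing.assert_allclose(fit.beta, beta_oracle, atol=1e-6)

    def test_zero_response(self, fixture_20rows):
        df = fixture_20rows.copy()
        df["phenotype"] = 0.0
        design = wlmm.build_design(df)
        fit = wlmm.fit(design, fixed_ratios=(0.0,))
        np.testing.assert_allclose(fit.beta, 0.0, atol=1e-10)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_profile_matches_dense_grid_search(self):
        """Brute-force maximizer of the same REML criterion on a tiny instance."""
        cfg = simulate.SimConfig(
            n_families=5, family_size=(2, 3), measures_per_person=(1, 2),
            family_var=0.4, resid_var=0.6,
        )
        df, _ = simulate.simulate_measures(cfg, seed=21)
        df = _standardized(df)
        design = wlmm.build_design(df)
        w = np.random.default_rng(3).uniform(0.3, 1.0, design.n_rows)
        fit = wlmm.fit(design, weights=w, method="reml")

        grid = np.exp(np.linspace(-12, 6, 4000))
        crits = [
            dense_reml_neg2(design.X, design.y, w, design.family_codes, (g,))
            for g in grid
        ]
        g_best = grid[int(np.argmin(crits))]
        beta_grid = dense_gls(
            design.X, design.y, w, design.family_codes, g_best, 0.0, 1.0
        )
        np.testing.assert_allclose(fit.beta, beta_grid, atol=1e-3)

    def test_weight_scaling_invariance(self, fixture_20rows):
        design = wlmm.build_design(fixture_20rows)
        w = np.random.default_rng(4).uniform(0.2, 1.5, design.n_rows)
        f1 = wlmm.fit(design, weights=w)
        f2 = wlmm.fit(design, weights=7.3 * w)
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-6)

    def test_zero_weight_equals_deletion(self, small_standardized):
        df, _ = small_standardized
        df = df.iloc[:200].reset_index(drop=True)
        design = wlmm.build_design(df)
        w = np.ones(design.n_rows)
        w[10:30] = 0.0
        f_zero = wlmm.fit(design, weights=w)
        kept = df.drop(index=range(10, 30)).reset_index(drop=True)
        f_del = wlmm.fit(wlmm.build_design(kept))
        np.testing.assert_allclose(f_zero.beta, f_del.beta, atol=1e-8)
        assert f_zero.n_rows == f_del.n_rows

    def test_ml_nesting(self, small_standardized):
        df, _ = small_standardized
        df = df.iloc[:400]
        design = wlmm.build_design(df)
        full = wlmm.fit(design, method="ml")
        reduced = wlmm.fit(design.drop_term("pgs"), method="ml")
        assert full.loglik >= reduced.loglik - 1e-8

    def test_variance_components_nonnegative(self, small_standardized):
        df, _ = small_standardized
        fit = wlmm.fit(wlmm.build_design(df.iloc[:300]))
        assert fit.sigma2 >= 0 and fit.family_var >= 0

    def test_recovers_family_variance(self, small_standardized):
        df, truth = small_standardized
        fit = wlmm.fit(wlmm.build_design(df))
        share = fit.family_var / fit.total_variance
        true_share = truth["family_var"] / truth["analytic_phenotype_variance"]
        assert share == pytest.approx(true_share, abs=0.08)

    def test_bad_method(self, fixture_20rows):
        with pytest.raises(InputError):
            wlmm.fit(wlmm.build_design(fixture_20rows), method="mcmc")

    def test_misaligned_weights(self, fixture_20rows):
        design = wlmm.build_design(fixture_20rows)
        with pytest.raises(InputError):
            wlmm.fit(design, weights=np.ones(3))


class TestPseudoR2:
    def test_null_pgs_near_zero(self):
        cfg = simulate.SimConfig(
            n_families=1200, family_size=(2, 2), measures_per_person=(1, 2),
            beta_age=0.0,
        )
        df, _ = simulate.simulate_measures(cfg, seed=31)
        df = _standardized(df)
        design = wlmm.build_design(df)
        f1 = wlmm.fit(design)
        f0 = wlmm.fit(design.drop_term("pgs"))
        r2 = wlmm.pseudo_r2(f1, f0)
        assert abs(r2) < 0.005

    def test_matches_beta_squared(self):
        cfg = simulate.SimConfig(
            n_families=2500, family_size=(2, 2), measures_per_person=(1, 2),
            beta_age=0.05,
        )
        df, _ = simulate.simulate_measures(cfg, seed=37)
        df = _standardized(df)
        design = wlmm.build_design(df)
        f1 = wlmm.fit(design)
        f0 = wlmm.fit(design.drop_term("pgs"))
        r2 = wlmm.pseudo_r2(f1, f0)
        # analytic limit beta^2 for standardized outcome and PGS
        assert r2 == pytest.approx(0.05**2, abs=0.003)

    def test_mismatched_rows_raises(self, small_standardized):
        df, _ = small_standardized
        f1 = wlmm.fit(wlmm.build_design(df.iloc[:300]))
        f0 = wlmm.fit(wlmm.build_design(df.iloc[:200]))
        with pytest.raises(InputError):
            wlmm.pseudo_r2(f1, f0)
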