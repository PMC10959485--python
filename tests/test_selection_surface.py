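"""Selection gradients, Gamma conventions, canonical rotation, Mardia."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clinesel.datasets import published_selection_gradients
from clinesel.errors import DataError
from clinesel.selection_surface import (FitnessVector,
                                        GammaMatrix, StandardizedTraitTable,
                                        build_gamma_matrix, canonical_analysis,
                                        canonical_significance, full_canonical,
                                        linear_gradients, mardia_test,
                                        observed_index_ranges,
                                        quadratic_gradients, relative_fitness,
                                        significance_stars, standardize_traits,
                                        stationary_point)

TRAITS = ["BST", "FYH", "FFI", "SW"]


def trait_table(rng, n=200):
    df = pd.DataFrame(rng.standard_normal((n, 4)), columns=TRAITS,
                      index=[f"F{i}" for i in range(n)])
    return standardize_traits(df)


class TestStandardize:
    def test_divides_by_sd(self, rng):
        df = pd.DataFrame({"a": 2.0 * rng.standard_normal(50),
                           "b": rng.standard_normal(50)})
        stt = standardize_traits(df)
        assert np.allclose(stt.values.std(ddof=1), 1.0, atol=1e-10)
        assert np.allclose(stt.values["a"], df["a"] / df["a"].std(ddof=1))

    def test_idempotent(self, rng):
        df = pd.DataFrame({"a": rng.normal(3, 5, 40)})
        once = standardize_traits(df)
        twice = standardize_traits(once.values)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_zero_sd_names_trait(self):
        df = pd.DataFrame({"ok": [1.0, 2, 3, 4], "flat": [1.0, 1, 1, 1]})
        with pytest.raises(DataError, match="flat"):
            standardize_traits(df)

    def test_gradient_scaling_identity(self, rng):
        # beta on standardized traits = beta on raw traits times trait SD
        raw = pd.DataFrame(rng.standard_normal((300, 4)) * [2.0, 5.0, 0.5, 1.0],
                           columns=TRAITS)
        w_abs = 1.0 + 0.1 * raw["FYH"] + rng.normal(0, 0.05, 300)
        fv = relative_fitness(pd.Series(np.maximum(w_abs, 0)), "height-including-dead")
        raw_stt = StandardizedTraitTable(values=raw, sds=pd.Series(1.0, TRAITS),
                                         centered=False)
        lg_raw = linear_gradients(fv, raw_stt)
        lg_std = linear_gradients(fv, standardize_traits(raw))
        sds = raw.std(ddof=1)
        assert np.allclose(lg_std.beta, lg_raw.beta * sds, rtol=1e-8)


class TestRelativeFitness:
    def test_divides_by_mean(self):
        fv = relative_fitness(pd.Series([2.0, 4.0, 6.0]), "survival-proportion")
        assert np.allclose(fv.w, [0.5, 1.0, 1.5])
        assert fv.mean_absolute == 4.0

    def test_constant_and_mean_one(self, rng):
        assert (relative_fitness(pd.Series([3.0] * 5), "x").w == 1.0).all()
        W = pd.Series(rng.uniform(0.1, 2.0, 100))
        assert relative_fitness(W, "x").w.mean() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DataError):
            relative_fitness(pd.Series([0.0, 0.0]), "x")


class TestGradientModels:
    def test_exact_linear_recovery(self, rng):
        stt = trait_table(rng)
        w = 1.0 + 0.2 * stt.values["FYH"]
        fv = FitnessVector(w=w, definition="x", mean_absolute=1.0)
        lg = linear_gradients(fv, stt)
        assert np.allclose(lg.beta, [0, 0.2, 0, 0], atol=1e-12)
        assert lg.alpha == pytest.approx(1.0, abs=1e-12)

    def test_normal_equations_oracle(self, rng):
        stt = trait_table(rng, 80)
        w = pd.Series(rng.uniform(0.5, 1.5, 80), index=stt.values.index)
        fv = FitnessVector(w=w, definition="x", mean_absolute=1.0)
        lg = linear_gradients(fv, stt)
        X = np.column_stack([np.ones(80), stt.values.to_numpy()])
        beta = np.linalg.solve(X.T @ X, X.T @ w.to_numpy())
        assert np.allclose(lg.beta, beta[1:], atol=1e-10)

    def test_quadratic_doubling_convention(self, rng):
        stt = trait_table(rng)
        w = 1.0 + stt.values["BST"] ** 2
        fv = FitnessVector(w=w, definition="x", mean_absolute=1.0)
        qg = quadratic_gradients(fv, stt)
        # raw OLS coefficient is 1.0 = (1/2) gamma_11 -> reported gamma_11 = 2
        assert qg.gamma_ii["BST"] == pytest.approx(2.0, abs=1e-10)
        assert qg.doubling_applied

    def test_pure_cross_term(self, rng):
        stt = trait_table(rng)
        w = 1.0 + stt.values["BST"] * stt.values["FYH"]
        fv = FitnessVector(w=w, definition="x", mean_absolute=1.0)
        qg = quadratic_gradients(fv, stt)
        assert qg.gamma_off["BST:FYH"] == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(qg.gamma_ii, 0.0, atol=1e-10)

    def test_beta_star_equals_beta_when_surface_linear(self, rng):
        stt = trait_table(rng)
        w = 1.0 + 0.15 * stt.values["BST"] - 0.05 * stt.values["SW"]
        fv = FitnessVector(w=w, definition="x", mean_absolute=1.0)
        lg = linear_gradients(fv, stt)
        qg = quadratic_gradients(fv, stt)
        assert np.allclose(lg.beta, qg.beta_star, atol=1e-10)

    def test_rank_deficiency_reported(self, rng):
        vals = trait_table(rng).values.copy()
        vals["SW"] = vals["BST"]
        stt = StandardizedTraitTable(vals, pd.Series(1.0, TRAITS), False)
        fv = FitnessVector(w=pd.Series(1.0, index=vals.index), definition="x",
                           mean_absolute=1.0)
        with pytest.raises(DataError, match="[Vv]ariance_inflation|rank"):
            linear_gradients(fv, stt)


class TestMardia:
    def test_kurtosis_identity_for_mvn(self, rng):
        X = pd.DataFrame(rng.standard_normal((4000, 4)), columns=TRAITS)
        res = mardia_test(X)
        assert res.kurtosis_stat == pytest.approx(24.0, rel=0.05)
        assert res.skewness_p > 0.001

    def test_detects_skew(self, rng):
        X = pd.DataFrame(np.exp(rng.standard_normal((500, 4))), columns=TRAITS)
        res = mardia_test(X)
        assert res.skewness_p < 0.01
        assert not res.multivariate_normal

    def test_minimal_sample_runs(self, rng):
        X = pd.DataFrame(rng.standard_normal((6, 4)), columns=TRAITS)
        res = mardia_test(X)
        assert 0 <= res.skewness_p <= 1 and 0 <= res.kurtosis_p <= 1

    def test_singular_covariance_rejected(self, rng):
        a = rng.standard_normal(30)
        X = pd.DataFrame({"a": a, "b": a, "c": rng.standard_normal(30)})
        with pytest.raises(DataError):
            mardia_test(X)


def qg_from_matrix(beta, gamma_full):
    """Pack arrays into a QuadraticGradients for matrix-construction tests."""
    from clinesel.selection_surface import QuadraticGradients
    from itertools import combinations
    names = TRAITS
    off = {}
    for a, b in combinations(range(4), 2):
        off[f"{names[a]}:{names[b]}"] = gamma_full[a, b]
    dummy = pd.Series(0.0, index=names)
    return QuadraticGradients(
        beta_star=pd.Series(beta, index=names),
        gamma_ii=pd.Series(np.diag(gamma_full), index=names),
        gamma_off=pd.Series(off), se=dummy, p=dummy, alpha=1.0,
        doubling_applied=True, traits=tuple(names))


class TestGammaAndCanonical:
    def test_published_halved_diagonal(self):
        pub = published_selection_gradients("height-including-dead")
        gm = build_gamma_matrix(qg_from_matrix(pub["beta"], pub["gamma_full"]),
                                "halved")
        expected = [-1.055e-4, -5.4e-4, -2.84e-3, 4.19e-6]
        assert np.allclose(np.diag(gm.matrix), expected, rtol=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_convention_doubling(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.standard_normal((4, 4))
        g = g + g.T
        qg = qg_from_matrix(rng.standard_normal(4), g)
        halved = build_gamma_matrix(qg, "halved").matrix.to_numpy()
        full = build_gamma_matrix(qg, "full").matrix.to_numpy()
        assert np.allclose(halved, halved.T, atol=1e-15)
        assert np.allclose(full, 2 * halved, atol=1e-15)
        assert np.allclose(np.sort(np.linalg.eigvalsh(full)),
                           2 * np.sort(np.linalg.eigvalsh(halved)), atol=1e-12)

    def test_unknown_convention(self):
        qg = qg_from_matrix(np.zeros(4), np.eye(4))
        with pytest.raises(DataError):
            build_gamma_matrix(qg, "thirds")

    def test_diagonal_gamma_gives_identity_rotation(self):
        diag = np.diag([0.4, -0.2, 0.1, -0.5])
        gm = GammaMatrix(pd.DataFrame(diag, index=TRAITS, columns=TRAITS), "full")
        dec = canonical_analysis(gm, pd.Series([1.0, 2, 3, 4], index=TRAITS))
        assert np.allclose(dec.lam, [0.4, 0.1, -0.2, -0.5])
        P = dec.M.to_numpy()
        assert np.allclose(np.abs(P).sum(axis=0), 1.0)   # permutation matrix
        # theta permutes beta accordingly
        assert set(np.round(dec.theta, 9)) == {1.0, 2.0, 3.0, 4.0}

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_reconstruction_and_trace(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.standard_normal((4, 4))
        g = (g + g.T) / 2
        gm = GammaMatrix(pd.DataFrame(g, index=TRAITS, columns=TRAITS), "halved")
        dec = canonical_analysis(gm, pd.Series(rng.standard_normal(4), index=TRAITS))
        M = dec.M.to_numpy()
        lam = dec.lam.to_numpy()
        assert np.allclose(M.T @ M, np.eye(4), atol=1e-10)
        assert np.allclose(M @ np.diag(lam) @ M.T, g, atol=1e-10)
        assert np.sum(lam) == pytest.approx(np.trace(g), abs=1e-12)
        assert np.all(np.diff(lam) <= 1e-15)

    def test_rotation_preserves_fitted_surface(self, rng):
        # fitted fitness from (beta*, Gamma) equals fitness from (theta, Lambda)
        stt = trait_table(rng, 300)
        f = stt.values
        w = (1.0 + 0.1 * f["BST"] - 0.2 * f["FFI"] ** 2
             + 0.15 * f["FYH"] * f["SW"] + rng.normal(0, 0.05, 300))
        fv = FitnessVector(w=pd.Series(w, index=f.index), definition="x",
                           mean_absolute=1.0)
        qg = quadratic_gradients(fv, stt)
        gm = build_gamma_matrix(qg, "halved")
        dec = canonical_analysis(gm, qg.beta_star)
        F = f.to_numpy()
        fit_orig = (qg.alpha + F @ qg.beta_star.to_numpy()
                    + np.einsum("ni,ij,nj->n", F, gm.matrix.to_numpy(), F))
        Z = F @ dec.M.to_numpy()
        fit_rot = (qg.alpha + Z @ dec.theta.to_numpy()
                   + np.einsum("ni,i,ni->n", Z, dec.lam.to_numpy(), Z))
        assert np.allclose(fit_orig, fit_rot, atol=1e-10)

    def test_asymmetric_input_rejected(self):
        m = np.eye(4)
        m[0, 1] = 1e-6
        with pytest.raises(DataError):
            GammaMatrix(pd.DataFrame(m, index=TRAITS, columns=TRAITS), "full")


class TestCanonicalSignificance:
    def test_identity_rotation_reproduces_pvalues(self, rng):
        stt = trait_table(rng, 300)
        w = 1.0 + 0.1 * stt.values["BST"] + rng.normal(0, 0.1, 300)
        fv = FitnessVector(w=pd.Series(w, index=stt.values.index),
                           definition="x", mean_absolute=1.0)
        qg = quadratic_gradients(fv, stt)
        I = pd.DataFrame(np.eye(4), index=TRAITS, columns=TRAITS)
        theta_p, lambda_p, _ = canonical_significance(fv, stt, I)
        assert np.allclose(theta_p.to_numpy(),
                           qg.p[list(TRAITS)].to_numpy(), atol=1e-10)
        assert np.allclose(lambda_p.to_numpy(),
                           qg.p[[f"{t}^2" for t in TRAITS]].to_numpy(), atol=1e-10)

    def test_rotated_regression_spans_same_space(self, rng):
        stt = trait_table(rng, 300)
        w = (1.0 - 0.3 * stt.values["FFI"] ** 2
             + rng.normal(0, 0.1, 300))
        fv = FitnessVector(w=pd.Series(w, index=stt.values.index),
                           definition="x", mean_absolute=1.0)
        dec = full_canonical(fv, stt)
        _, _, qg_rot = canonical_significance(fv, stt, dec.M)
        qg = quadratic_gradients(fv, stt)
        # fitted values agree because the quadratic design spans are equal
        from clinesel.selection_surface import _quadratic_design
        import statsmodels.api as sm
        X = sm.add_constant(_quadratic_design(stt.values))
        fit_o = sm.OLS(fv.w, X).fit().fittedvalues
        Z = pd.DataFrame(stt.values.to_numpy() @ dec.M.to_numpy(),
                         index=stt.values.index, columns=dec.M.columns)
        fit_r = sm.OLS(fv.w, sm.add_constant(_quadratic_design(Z))).fit().fittedvalues
        assert np.allclose(fit_o, fit_r, atol=1e-10)

    def test_power_for_strong_curvature(self, rng):
        # a true lambda of -0.4 at n=500 should be detected most of the time
        hits = 0
        reps = 100
        for _ in range(reps):
            f = pd.DataFrame(rng.standard_normal((500, 4)), columns=TRAITS)
            w = 2.0 - 0.4 * f["FFI"] ** 2 + rng.normal(0, 0.5, 500)
            fv = FitnessVector(w=pd.Series(w.to_numpy(), index=f.index),
                               definition="x", mean_absolute=1.0)
            stt = StandardizedTraitTable(f, pd.Series(1.0, TRAITS), False)
            dec = full_canonical(fv, stt)
            lam_min_axis = dec.lam.idxmin()
            hits += dec.lambda_p[lam_min_axis] < 0.05
        assert hits >= 80


class TestStationaryPoint:
    def test_trivial_cases(self):
        z = stationary_point(pd.Series({"m1": 0.0}), pd.Series({"m1": -0.3}))
        assert z["m1"] == 0.0
        z = stationary_point(pd.Series({"m1": 0.2}), pd.Series({"m1": -0.1}))
        assert z["m1"] == pytest.approx(1.0)

    def test_zero_eigenvalue_flagged(self):
        z = stationary_point(pd.Series({"m1": 0.2, "m2": 0.1}),
                             pd.Series({"m1": 0.0, "m2": -0.5}))
        assert np.isnan(z["m1"]) and np.isfinite(z["m2"])

    def test_gradient_zero_at_stationary_point(self, rng):
        stt = trait_table(rng, 400)
        f = stt.values
        w = (1.0 + 0.05 * f["BST"] - 0.2 * f["BST"] ** 2 - 0.1 * f["FYH"] ** 2
             - 0.15 * f["FFI"] ** 2 - 0.05 * f["SW"] ** 2
             + rng.normal(0, 0.02, 400))
        fv = FitnessVector(w=pd.Series(w, index=f.index), definition="x",
                           mean_absolute=1.0)
        dec = full_canonical(fv, stt)
        # gradient of w = a + theta'z + z'Lambda z is theta + 2 Lambda z
        grad = dec.theta.to_numpy() + 2 * dec.lam.to_numpy() * dec.z_star.to_numpy()
        assert np.allclose(grad, 0.0, atol=1e-10)


class TestIndexRanges:
    def test_single_family(self):
        f = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], columns=TRAITS)
        stt = StandardizedTraitTable(f, pd.Series(1.0, TRAITS), False)
        M = pd.DataFrame(np.eye(4), index=TRAITS, columns=["m1", "m2", "m3", "m4"])
        r = observed_index_ranges(stt, M)
        assert (r["min"] == r["max"]).all()

    def test_brute_force_and_order_invariance(self, rng):
        f = pd.DataFrame(rng.standard_normal((50, 4)), columns=TRAITS)
        stt = StandardizedTraitTable(f, pd.Series(1.0, TRAITS), False)
        g = rng.standard_normal((4, 4))
        gm = GammaMatrix(pd.DataFrame((g + g.T) / 2, index=TRAITS, columns=TRAITS),
                         "halved")
        dec = canonical_analysis(gm, pd.Series(np.zeros(4), index=TRAITS))
        r = observed_index_ranges(stt, dec.M)
        Z = f.to_numpy() @ dec.M.to_numpy()
        assert np.allclose(r["min"], Z.min(axis=0))
        assert np.allclose(r["max"], Z.max(axis=0))
        shuffled = StandardizedTraitTable(f.sample(frac=1, random_state=0),
                                          pd.Series(1.0, TRAITS), False)
        r2 = observed_index_ranges(shuffled, dec.M)
        pd.testing.assert_frame_equal(r, r2)


def test_significance_star_banding():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.07) == "."
    assert significance_stars(0.5) == ""
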