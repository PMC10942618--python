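"""GLM fitting, model comparison, permutation p-values, FDR, volumes, outliers."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from fosmap import (
    FULL_TERMS,
    NULL_TERMS,
    AnimalDesign,
    CountMatrix,
    ValidationError,
    build_design,
    compare_models,
    compare_region_volumes,
    detect_count_outliers,
    fdr_adjust,
    fit_quasipoisson,
    permutation_screen,
    sex_interaction_screen,
)
from fosmap.glm import DesignRankWarning, GlmError


def poisson_mle_oracle(y, X):
    """Independent direct maximization of the Poisson log-likelihood."""
    y = np.asarray(y, dtype=float)

    def nll(b):
        eta = X @ b
        return float(np.sum(np.exp(eta)) - y @ eta)

    def grad(b):
        return X.T @ (np.exp(X @ b) - y)

    def hess(b):
        return (X * np.exp(X @ b)[:, None]).T @ X

    res = optimize.minimize(
        nll, np.zeros(X.shape[1]), jac=grad, hess=hess, method="Newton-CG",
        options={"xtol": 1e-14, "maxiter": 500},
    )
    return res.x


class TestFit:
    def test_intercept_only_closed_form(self):
        """Intercept-only MLE is log(mean); Pearson dispersion is chi2/(n-1)."""
        fit = fit_quasipoisson(np.array([2, 4]), np.ones((2, 1)))
        assert fit.coefficients["x0"] == pytest.approx(np.log(3.0), abs=1e-10)
        assert fit.pearson_dispersion == pytest.approx(2.0 / 3.0, abs=1e-10)
        assert fit.df_residual == 1

    def test_group_saturated_fit(self):
        y = np.array([2, 2, 8, 8])
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        fit = fit_quasipoisson(y, X)
        assert fit.coefficients["x0"] == pytest.approx(np.log(2.0), abs=1e-10)
        assert fit.coefficients["x1"] == pytest.approx(np.log(4.0), abs=1e-10)
        assert fit.deviance == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed,n,p", [(0, 20, 3), (1, 30, 4), (2, 25, 2)])
    def test_matches_likelihood_oracle(self, seed, n, p):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = rng.poisson(np.exp(0.5 + X[:, 1:] @ rng.normal(0, 0.3, p - 1)) + 1)
        fit = fit_quasipoisson(y, X)
        ref = poisson_mle_oracle(y, X)
        np.testing.assert_allclose(list(fit.coefficients.values()), ref, atol=1e-8)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
        y = rng.poisson(np.exp(1.0 + 0.3 * X[:, 1]))
        fit = fit_quasipoisson(y, X)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(list(fit.coefficients.values()), ref.params, atol=1e-8)
        assert fit.deviance == pytest.approx(ref.deviance, abs=1e-8)
        assert fit.pearson_dispersion == pytest.approx(
            ref.pearson_chi2 / ref.df_resid, abs=1e-8
        )

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(GlmError, match="collinear"):
            fit_quasipoisson(np.arange(10), X, names=["const", "a", "a_twice"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            fit_quasipoisson(np.array([-1, 2]), np.ones((2, 1)))

    def test_point_estimates_invariant_to_overdispersion(self):
        """NB data at two dispersion levels: estimates centered on the same truth."""
        rng = np.random.default_rng(42)
        n = 400
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        mu = np.exp(2.0 + 0.5 * x)
        for theta in (50.0, 2.0):
            betas = []
            for _ in range(20):
                y = rng.negative_binomial(theta, theta / (theta + mu))
                betas.append(fit_quasipoisson(y, X).coefficients["x1"])
            assert np.mean(betas) == pytest.approx(0.5, abs=0.05)


class TestDesignMatrix:
    def test_null_and_full_shapes(self, small_design):
        Xn, names_n = build_design(small_design, NULL_TERMS)
        Xf, names_f = build_design(small_design, FULL_TERMS)
        assert Xn.shape == (24, 5) and names_n == ["const", "S", "T", "T2", "B"]
        assert Xf.shape == (24, 9)

    def test_all_sibling_partner_column_warns(self, small_design):
        sibs = [r for r in small_design if r.partner == "sibling"]
        with pytest.warns(DesignRankWarning):
            build_design(sibs, ("P",))

    def test_unknown_term_rejected(self, small_design):
        with pytest.raises(GlmError, match="unknown"):
            build_design(small_design, ("Q",))


class TestCompareModels:
    def test_identical_models_rejected(self, small_design):
        y = np.arange(24) + 1
        with pytest.raises(GlmError, match="strict subset"):
            compare_models(y, small_design, FULL_TERMS, FULL_TERMS)

    def test_f_zero_when_added_column_uninformative(self, small_design):
        """Constant counts: both models fit the mean exactly, so F = 0."""
        y = np.full(24, 7)
        mc = compare_models(y, small_design)
        assert mc.f_stat == 0.0

    def test_f_matches_deviance_formula(self, small_design):
        """F must equal the hand-computed deviance/dispersion formula to 1e-10."""
        rng = np.random.default_rng(5)
        y = rng.poisson(30, size=24)
        Xn, nn = build_design(small_design, NULL_TERMS)
        Xf, nf = build_design(small_design, FULL_TERMS)
        fn = fit_quasipoisson(y, Xn, nn)
        ff = fit_quasipoisson(y, Xf, nf)
        expected = (fn.deviance - ff.deviance) / 4 / ff.pearson_dispersion
        mc = compare_models(y, small_design)
        assert mc.f_stat == pytest.approx(expected, abs=1e-10)
        assert mc.df_num == 4
        assert mc.direction == int(np.sign(ff.coefficients["P"]))

    def test_unit_dispersion_reduces_to_lr_over_df(self, small_design):
        rng = np.random.default_rng(6)
        y = rng.poisson(30, size=24)
        Xn, nn = build_design(small_design, NULL_TERMS)
        Xf, nf = build_design(small_design, FULL_TERMS)
        lr = fit_quasipoisson(y, Xn, nn).deviance - fit_quasipoisson(y, Xf, nf).deviance
        mc = compare_models(y, small_design, dispersion=1.0)
        assert mc.f_stat == pytest.approx(lr / 4, abs=1e-10)


def _counts(df_rows, design, n_rois, seed=0, mu=30):
    rng = np.random.default_rng(seed)
    return CountMatrix(
        pd.DataFrame(
            rng.poisson(mu, size=(len(design), n_rois)),
            index=[r.animal_id for r in design],
            columns=[f"r{i}" for i in range(n_rois)],
        )
    )


class TestPermutationScreen:
    def test_constant_counts_give_p_one(self, small_design):
        df = pd.DataFrame(
            {"flat": np.full(24, 9), "noisy": np.random.default_rng(0).poisson(20, 24)},
            index=[r.animal_id for r in small_design],
        )
        res, _ = permutation_screen(CountMatrix(df), small_design, n_perm=50, seed=1)
        flat = next(r for r in res if r.roi_id == "flat")
        assert flat.f_stat == 0.0 and flat.p_perm == 1.0

    def test_plus_one_rule_floor(self, small_design):
        cm = _counts(None, small_design, 3, seed=2)
        res, _ = permutation_screen(cm, small_design, n_perm=1, seed=3)
        for r in res:
            assert r.p_perm in (0.5, 1.0)
            assert r.n_permutations == 1

    def test_all_zero_roi_skipped(self, small_design):
        df = pd.DataFrame(
            {"dead": np.zeros(24, dtype=int),
             "alive": np.random.default_rng(1).poisson(20, 24)},
            index=[r.animal_id for r in small_design],
        )
        res, skipped = permutation_screen(CountMatrix(df), small_design, n_perm=10, seed=1)
        assert [r.roi_id for r in res] == ["alive"]
        assert skipped == [("dead", "all-zero counts")]

    def test_q_values_are_bh_of_p(self, small_design):
        cm = _counts(None, small_design, 8, seed=4)
        res, _ = permutation_screen(cm, small_design, n_perm=99, seed=5)
        p = np.array([r.p_perm for r in res])
        np.testing.assert_allclose([r.q_value for r in res], fdr_adjust(p), atol=1e-12)

    def test_deterministic_given_seed(self, small_design):
        cm = _counts(None, small_design, 5, seed=6)
        r1, _ = permutation_screen(cm, small_design, n_perm=30, seed=7)
        r2, _ = permutation_screen(cm, small_design, n_perm=30, seed=7)
        assert [(a.roi_id, a.p_perm) for a in r1] == [(b.roi_id, b.p_perm) for b in r2]


class TestSexInteractionScreen:
    def test_sex_swapped_duplicates_give_zero_f(self, small_design):
        """Duplicating each animal with sex flipped and identical counts kills PxS."""
        from dataclasses import replace

        rng = np.random.default_rng(8)
        base = rng.poisson(30, size=(24, 4))
        mirrored = []
        for i, r in enumerate(small_design):
            mirrored.append(replace(r, animal_id=f"{r.animal_id}x"))
            flipped = "F" if r.sex == "M" else "M"
            partner_pid = r.pair_id + "s"
            mirrored.append(
                replace(r, animal_id=f"{r.animal_id}y", sex=flipped, pair_id=partner_pid)
            )
        counts = np.repeat(base, 2, axis=0)
        cm = CountMatrix(
            pd.DataFrame(counts, index=[m.animal_id for m in mirrored],
                         columns=[f"r{i}" for i in range(4)])
        )
        res, _ = sex_interaction_screen(cm, mirrored, n_perm=20, seed=9)
        for r in res:
            assert r.f_stat == pytest.approx(0.0, abs=1e-6)

    def test_planted_interaction_ranks_first(self):
        """Regions with a planted PxS effect get the smallest permutation p."""
        rng = np.random.default_rng(10)
        rows = []
        for t in (1, 2, 3, 4):
            for m in range(6):
                pid = f"t{t}m{m}"
                rows.append(AnimalDesign(f"{pid}F", "F", "mate", t, m % 6 + 1, pid))
                rows.append(AnimalDesign(f"{pid}M", "M", "mate", t, m % 6 + 1, pid))
            for s in range(6):
                pid = f"t{t}s{s}"
                sex = "F" if s % 2 == 0 else "M"
                rows.append(AnimalDesign(f"{pid}a", sex, "sibling", t, s % 6 + 1, pid))
                rows.append(AnimalDesign(f"{pid}b", sex, "sibling", t, s % 6 + 1, pid))
        P = np.array([r.partner == "mate" for r in rows], dtype=float)
        S = np.array([r.sex == "M" for r in rows], dtype=float)
        mu = np.exp(np.log(40) + 0.5 * P * S)
        planted = rng.poisson(mu[:, None], size=(len(rows), 3))
        null = rng.poisson(40, size=(len(rows), 12))
        cm = CountMatrix(
            pd.DataFrame(np.hstack([planted, null]),
                         index=[r.animal_id for r in rows],
                         columns=[f"sig{i}" for i in range(3)] + [f"nul{i}" for i in range(12)])
        )
        res, _ = sex_interaction_screen(cm, rows, n_perm=200, seed=11)
        order = sorted(res, key=lambda r: (r.p_perm, -r.f_stat))
        assert {r.roi_id for r in order[:3]} == {"sig0", "sig1", "sig2"}


def bh_stepup_oracle(p):
    """Brute-force BH step-up definition over the sorted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


class TestFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_single_p_identity(self):
        assert fdr_adjust([0.5])[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 60))
        np.testing.assert_allclose(fdr_adjust(p), bh_stepup_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_adjust([0.5, 1.2])


class TestVolumes:
    def test_identical_groups_give_zero_z(self):
        vols = pd.DataFrame(
            [[100, 200, 300, 100, 200, 300], [50, 60, 70, 50, 60, 70]],
            index=["rA", "rB"],
        )
        group = np.array(["a", "a", "a", "b", "b", "b"])
        out = compare_region_volumes(vols, group)
        np.testing.assert_allclose(out["z"], 0.0, atol=1e-5)

    def test_twofold_difference_recovered(self):
        rng = np.random.default_rng(12)
        n = 60
        theta = 20.0
        mu = np.where(np.arange(2 * n) < n, 500.0, 1000.0)
        y = rng.negative_binomial(theta, theta / (theta + mu))
        vols = pd.DataFrame([y], index=["r"])
        group = np.array(["g1"] * n + ["g2"] * n)  # g2 is the doubled group
        out = compare_region_volumes(vols, group)
        coef = out.loc[0, "coef"]
        # s.e. of the log fold change is ~sqrt(2 * (1/mu + 1/theta) / n)
        se = np.sqrt(2 * (1 / 500 + 1 / theta) / n)
        assert abs(coef - np.log(2.0)) < 3 * se

    def test_relative_offset_cancels_proportional_volumes(self):
        rng = np.random.default_rng(13)
        whole = np.concatenate([rng.integers(9000, 11000, 20),
                                rng.integers(18000, 22000, 20)])
        vols = pd.DataFrame([np.round(whole * 0.1).astype(int)], index=["r"])
        group = np.array(["a"] * 20 + ["b"] * 20)
        out = compare_region_volumes(vols, group, relative=True, whole_brain=whole)
        assert abs(out.loc[0, "z"]) < 1.0

    def test_too_few_animals_skipped(self):
        vols = pd.DataFrame([[100, 110, 120]], index=["r"])
        out = compare_region_volumes(vols, np.array(["a", "a", "b"]))
        assert out.loc[0, "skipped_reason"] is not None


def esd_oracle(x, max_k, alpha):
    """Independent re-implementation of the generalized ESD recursion."""
    x = list(map(float, x))
    n = len(x)
    stats_out = []
    for i in range(1, max_k + 1):
        arr = np.array(x)
        mean, sd = arr.mean(), arr.std(ddof=1)
        dev = np.abs(arr - mean)
        j = int(np.argmax(dev))
        r = dev[j] / sd
        pt = 1 - alpha / (2 * (n - i + 1))
        t = stats.t.ppf(pt, n - i - 1)
        lam = (n - i) * t / np.sqrt((n - i - 1 + t**2) * (n - i + 1))
        stats_out.append((r, lam))
        del x[j]
    return stats_out


class TestOutliers:
    def test_single_gross_outlier_flagged(self):
        rng = np.random.default_rng(14)
        flagged_right = 0
        for rep in range(20):
            x = np.append(rng.normal(0, 1, 50), 100.0)
            res = detect_count_outliers(x, max_k=3, alpha=0.05)
            if res.flagged == [50]:
                flagged_right += 1
        assert flagged_right >= 19

    def test_constant_data_notice(self):
        res = detect_count_outliers(np.full(20, 5.0), max_k=3)
        assert res.flagged == [] and "zero variance" in res.notice

    def test_matches_esd_oracle(self):
        rng = np.random.default_rng(15)
        x = np.concatenate([rng.normal(10, 2, 18), [40.0, 55.0]])
        res = detect_count_outliers(x, max_k=5, alpha=0.05)
        oracle = esd_oracle(x, 5, 0.05)
        np.testing.assert_allclose(res.r_statistics, [r for r, _ in oracle], atol=1e-10)
        np.testing.assert_allclose(res.critical_values, [l for _, l in oracle], atol=1e-10)

    def test_max_k_guard(self):
        with pytest.raises(ValidationError):
            detect_count_outliers(np.arange(5.0), max_k=3)
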