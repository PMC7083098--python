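"""REML engine: closed-form, cross-library and structural oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import block_diag

from fishid import datasets, matrix_compare
from fishid import mixed_models as mm
from fishid.mixed_models import _prepare, _reml_components

from conftest import analysis_scale, simulate_two_trait

TRAITS = ["TL", "Act", "AC", "TIM"]


# ---------------------------------------------------------------------------
# Univariate oracles
# ---------------------------------------------------------------------------

class TestUnivariate:
    def test_balanced_anova_closed_form(self):
        # balanced two-way layout: REML variance components equal the ANOVA
        # estimators computed here by brute force
        spec = datasets.default_species_spec("Xiphophorus maculatus",
                                             n_individuals=60, trials=4,
                                             group_size=1)  # order constant
        tab = analysis_scale(datasets.simulate_species(spec, seed=31))
        fit = mm.fit_univariate(tab, "AC")

        y = tab.pivot_table(index="fish_id", columns="repeat", values="AC").to_numpy()
        n, k = y.shape
        ind_mean = y.mean(axis=1)
        rep_mean = y.mean(axis=0)
        grand = y.mean()
        resid = y - ind_mean[:, None] - rep_mean[None, :] + grand
        mse = (resid ** 2).sum() / ((n - 1) * (k - 1))
        msa = k * ind_mean.var(ddof=1)
        v_i = max(0.0, (msa - mse) / k)
        assert fit.V_R == pytest.approx(mse, abs=1e-4)
        assert fit.V_I == pytest.approx(v_i, abs=1e-4)

    def test_matches_statsmodels_mixedlm(self, xh_table):
        smf = pytest.importorskip("statsmodels.formula.api")
        fit = mm.fit_univariate(xh_table, "TIM")
        d = xh_table.copy()
        d["rep"] = d["repeat"].astype(str)
        m = smf.mixedlm("TIM ~ C(rep) + order_in_group", d,
                        groups=d["fish_id"]).fit(reml=True)
        assert fit.V_I == pytest.approx(float(m.cov_re.iloc[0, 0]), abs=1e-5)
        assert fit.V_R == pytest.approx(float(m.scale), abs=1e-5)
        assert fit.reml_loglik == pytest.approx(float(m.llf), abs=1e-5)

    def test_parameter_recovery_repeatability(self):
        # V_I=0.3, V_R=0.7 truth; estimate should land near rho=0.3
        G = np.array([[0.3]])
        R = np.array([[0.7]])
        tab = simulate_two_trait(500, 5, G, R, seed=41, labels=("y",))
        fit = mm.fit_univariate(tab, "y")
        assert 0.25 < mm.repeatability(fit) < 0.35

    def test_pure_individual_signal_repeatability_one(self):
        rng = np.random.default_rng(0)
        n, k = 40, 3
        u = rng.normal(size=n)
        tab = pd.DataFrame({
            "fish_id": np.repeat([f"f{i}" for i in range(n)], k),
            "order_in_group": 1, "group": 1,
            "repeat": np.tile([1, 2, 3], n),
            "y": np.repeat(u, k),
        })
        fit = mm.fit_univariate(tab, "y")
        assert mm.repeatability(fit) > 0.999

    def test_row_order_invariance(self, xh_table):
        fit = mm.fit_univariate(xh_table, "TL")
        shuffled = xh_table.sample(frac=1.0, random_state=7)
        fit2 = mm.fit_univariate(shuffled, "TL")
        assert fit2.V_I == pytest.approx(fit.V_I, abs=1e-6)
        assert fit2.V_R == pytest.approx(fit.V_R, abs=1e-6)

    def test_repeatability_algebra(self):
        f = mm.UnivariateFit("t", 1.0, 1.0, {}, 0.0, True, 10, 20)
        assert mm.repeatability(f) == 0.5
        f.V_I = 0.0
        assert mm.repeatability(f) == 0.0
        reps = [mm.repeatability(mm.UnivariateFit("t", v, 0.7, {}, 0, True, 1, 2))
                for v in np.linspace(0, 3, 7)]
        assert np.all(np.diff(reps) > 0)


class TestMixtureLrt:
    def test_point_mass_and_half_chi2(self):
        stat, p = mm.lrt_mixture_p(-10.0, -10.0)
        assert stat == 0.0 and p == 0.5
        stat, p = mm.lrt_mixture_p(-10.0, -10.0 - 2.706 / 2)
        assert p == pytest.approx(0.05, abs=2e-4)

    def test_monotone_and_order_check(self):
        ps = [mm.lrt_mixture_p(0.0, -s / 2)[1] for s in np.linspace(0, 10, 11)]
        assert np.all(np.diff(ps) < 0)
        with pytest.raises(ValueError):
            mm.lrt_mixture_p(-20.0, -10.0)


# ---------------------------------------------------------------------------
# Restricted-likelihood value and gradient
# ---------------------------------------------------------------------------

def _naive_reml_neg2(tab, traits, G, R):
    """Dense-joint-system restricted likelihood, built independently of the
    grouped Kronecker evaluation: stack all observations, form the full
    block-diagonal covariance and apply the generic REML formula."""
    tab = tab.sort_values(["fish_id", "repeat"], kind="mergesort")
    T = len(traits)
    blocks, Xrows, yrows = [], [], []
    for _, sub in tab.groupby("fish_id", sort=True):
        n = len(sub)
        blocks.append(np.kron(np.eye(n), R) + np.kron(np.ones((n, n)), G))
        levels = np.sort(tab["repeat"].unique())
        for _, row in sub.iterrows():
            x = [1.0] + [1.0 * (row["repeat"] == l) for l in levels[1:]]
            x.append(float(row["order_in_group"]))
            for t in range(T):
                xr = np.zeros(T * len(x))
                xr[t * len(x):(t + 1) * len(x)] = x
                Xrows.append(xr)
            yrows.extend(float(row[c]) for c in traits)
    V = block_diag(*blocks)
    X = np.array(Xrows)
    y = np.array(yrows)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    M, q = len(y), X.shape[1]
    return ld_v + ld_x + r @ Vi @ r + (M - q) * np.log(2 * np.pi)


class TestRestrictedLikelihood:
    def test_matches_naive_dense_construction(self):
        spec = datasets.default_species_spec("Xenotoca eiseni",
                                             n_individuals=8, trials=3)
        tab = analysis_scale(datasets.simulate_species(spec, seed=51))
        rng = np.random.default_rng(1)
        A = rng.standard_normal((4, 4))
        G = A @ A.T * 0.1
        B = rng.standard_normal((4, 4))
        R = B @ B.T * 0.2 + 0.2 * np.eye(4)
        prep = _prepare(tab, TRAITS)
        fast, _, _, _ = _reml_components([prep], G, [R], want_grad=False)
        slow = _naive_reml_neg2(tab, TRAITS, G, R)
        assert fast == pytest.approx(slow, abs=1e-7)

    def test_gradient_matches_central_differences(self):
        spec = datasets.default_species_spec("Xiphophorus hellerii",
                                             n_individuals=25, trials=3)
        tab = analysis_scale(datasets.simulate_species(spec, seed=52))
        prep = _prepare(tab, TRAITS)
        rng = np.random.default_rng(2)
        A = rng.standard_normal((4, 4))
        G = A @ A.T * 0.1
        B = rng.standard_normal((4, 4))
        R = B @ B.T * 0.3 + 0.3 * np.eye(4)
        _, gG, gRs, _ = _reml_components([prep], G, [R])
        eps = 1e-5
        for a in range(4):
            for b in range(a + 1):
                E = np.zeros((4, 4))
                E[a, b] = E[b, a] = eps
                want = gG[a, b] + gG[b, a] if a != b else gG[a, a]
                fp = _reml_components([prep], G + E, [R], want_grad=False)[0]
                fm = _reml_components([prep], G - E, [R], want_grad=False)[0]
                assert (fp - fm) / (2 * eps) == pytest.approx(
                    want, rel=2e-3, abs=1e-4)
                want = gRs[0][a, b] + gRs[0][b, a] if a != b else gRs[0][a, a]
                fp = _reml_components([prep], G, [R + E], want_grad=False)[0]
                fm = _reml_components([prep], G, [R - E], want_grad=False)[0]
                assert (fp - fm) / (2 * eps) == pytest.approx(
                    want, rel=2e-3, abs=1e-4)


# ---------------------------------------------------------------------------
# Multivariate fits
# ---------------------------------------------------------------------------

class TestMultivariate:
    def test_single_trait_call_equals_univariate(self, xh_table):
        uni = mm.fit_univariate(xh_table, "Act")
        multi = mm.fit_multivariate(xh_table, traits=["Act"])
        assert multi.ID[0, 0] == pytest.approx(uni.V_I, abs=1e-6)
        assert multi.R[0, 0] == pytest.approx(uni.V_R, abs=1e-6)
        assert multi.reml_loglik == pytest.approx(uni.reml_loglik, abs=1e-6)

    def test_estimates_symmetric_psd_by_construction(self, xh_table):
        fit = mm.fit_multivariate(xh_table)
        assert np.array_equal(fit.ID, fit.ID.T)
        assert np.array_equal(fit.R, fit.R.T)
        assert np.linalg.eigvalsh(fit.ID).min() >= -1e-12
        assert np.linalg.eigvalsh(fit.R).min() > 0

    def test_nesting_monotone_loglik(self, xh_table):
        full = mm.fit_multivariate(xh_table)
        diag = mm.fit_multivariate(xh_table, constrain_diagonal=True)
        assert full.reml_loglik >= diag.reml_loglik - 1e-6
        stat, df, p = mm.lrt_id_covariances(full, diag)
        assert df == 6 and 0 <= p <= 1

    def test_identical_models_give_null_lrt(self, xh_table):
        full = mm.fit_multivariate(xh_table)
        stat, df, p = mm.lrt_id_covariances(full, full)
        assert stat == 0.0 and p == 1.0

    def test_strong_covariance_detected(self):
        # r = 0.9 everywhere in ID: the 6-df test should reject decisively
        G = 0.4 * (np.full((4, 4), 0.9) + 0.1 * np.eye(4))
        spec = datasets.SpeciesSpec(
            name="corr", n_individuals=200, trials_per_individual=4,
            group_size=8, mean_sl=30.0,
            trait_means=np.array([100.0, 40.0, 55.0, 8.0]),
            true_ID=G, true_R=0.6 * np.eye(4) + 0.1,
            repeat_effects=np.zeros((4, 4)),
            order_slope=np.zeros(4)).validate()
        tab = analysis_scale(datasets.simulate_species(spec, seed=61))
        full = mm.fit_multivariate(tab)
        diag = mm.fit_multivariate(tab, constrain_diagonal=True)
        _, _, p = mm.lrt_id_covariances(full, diag)
        assert p < 1e-3

    def test_leading_eigenvector_recovery(self):
        # generator built from the X. maculatus reference decomposition:
        # the dominant axis should be recovered to within 15 degrees
        spec = datasets.default_species_spec("Xiphophorus maculatus",
                                             n_individuals=500, trials=5)
        tab = analysis_scale(datasets.simulate_species(spec, seed=62))
        fit = mm.fit_multivariate(tab)
        est = matrix_compare.eigen_summary(fit.ID).leading
        true = matrix_compare.eigen_summary(spec.true_ID).leading
        assert matrix_compare.vector_angle(est, true) < 15.0

    def test_offdiagonal_null_recovery(self):
        spec = datasets.SpeciesSpec(
            name="diag", n_individuals=300, trials_per_individual=4,
            group_size=8, mean_sl=30.0,
            trait_means=np.array([100.0, 40.0, 55.0, 8.0]),
            true_ID=np.diag([0.3, 0.25, 0.35, 0.2]),
            true_R=0.6 * np.eye(4) + 0.1,
            repeat_effects=datasets.default_repeat_effects(4),
            order_slope=datasets.DEFAULT_ORDER_SLOPE).validate()
        tab = analysis_scale(datasets.simulate_species(spec, seed=63))
        fit = mm.fit_multivariate(tab)
        ens = mm.parametric_bootstrap(fit, n_draws=30, seed=64)
        se = ens.draws.std(axis=0, ddof=1)
        off = ~np.eye(4, dtype=bool)
        assert np.all(np.abs(fit.ID[off]) <= 3 * se[off] + 1e-9)


@pytest.fixture(scope="module")
def two_tables():
    sa = datasets.default_species_spec("Xiphophorus hellerii",
                                       n_individuals=60, trials=4)
    sb = datasets.default_species_spec("Xenotoca eiseni",
                                       n_individuals=60, trials=4)
    ta = analysis_scale(datasets.simulate_species(sa, seed=71))
    tb = analysis_scale(datasets.simulate_species(sb, seed=72))
    return ta, tb


class TestPairBlocked:
    def test_unconstrained_blocks_equal_separate_fits(self, two_tables):
        ta, tb = two_tables
        unc = mm.fit_pair_blocked(ta, tb)
        fa = mm.fit_multivariate(ta)
        fb = mm.fit_multivariate(tb)
        assert np.allclose(unc.ID[:4, :4], fa.ID, atol=1e-5)
        assert np.allclose(unc.ID[4:, 4:], fb.ID, atol=1e-5)
        assert np.allclose(unc.ID[:4, 4:], 0.0)
        assert unc.reml_loglik == pytest.approx(
            fa.reml_loglik + fb.reml_loglik, abs=1e-6)

    def test_equality_constraint_nested(self, two_tables):
        ta, tb = two_tables
        unc = mm.fit_pair_blocked(ta, tb)
        con = mm.fit_pair_blocked(ta, tb, constrain_equal=True)
        assert np.allclose(con.ID[:4, :4], con.ID[4:, 4:])
        assert unc.reml_loglik >= con.reml_loglik - 1e-6
        stat, df, p = mm.lrt_id_equality(unc, con)
        assert df == 10 and 0 <= p <= 1

    def test_different_id_detected(self):
        # traces differing by ~1 analysis-scale unit: decisive rejection
        G1 = 0.2 * np.eye(4) + 0.05
        G2 = G1 + 0.25 * np.eye(4)
        common = dict(trials_per_individual=4, group_size=8, mean_sl=30.0,
                      trait_means=np.array([100.0, 40.0, 55.0, 8.0]),
                      true_R=0.6 * np.eye(4) + 0.1,
                      repeat_effects=np.zeros((4, 4)),
                      order_slope=np.zeros(4))
        sa = datasets.SpeciesSpec(name="a", n_individuals=300, true_ID=G1,
                                  **common).validate()
        sb = datasets.SpeciesSpec(name="b", n_individuals=300, true_ID=G2,
                                  **common).validate()
        ta = analysis_scale(datasets.simulate_species(sa, seed=73))
        tb = analysis_scale(datasets.simulate_species(sb, seed=74))
        tb["fish_id"] = "b_" + tb["fish_id"]
        unc = mm.fit_pair_blocked(ta, tb)
        con = mm.fit_pair_blocked(ta, tb, constrain_equal=True)
        _, _, p = mm.lrt_id_equality(unc, con)
        assert p < 0.01

    def test_shared_individuals_rejected(self, two_tables):
        ta, _ = two_tables
        with pytest.raises(mm.DesignError):
            mm.fit_pair_blocked(ta, ta.copy())


class TestParametricBootstrap:
    def test_deterministic_and_psd(self, well_conditioned_spec):
        tab = analysis_scale(datasets.simulate_species(well_conditioned_spec,
                                                       seed=81))
        fit = mm.fit_multivariate(tab)
        e1 = mm.parametric_bootstrap(fit, n_draws=10, seed=5)
        e2 = mm.parametric_bootstrap(fit, n_draws=10, seed=5)
        assert np.allclose(e1.draws, e2.draws)
        for d in e1.draws:
            assert np.linalg.eigvalsh(d).min() >= -1e-10

    def test_ensemble_mean_near_point_estimate(self, well_conditioned_spec):
        # interior truth: bootstrap mean within 3 Monte-Carlo SE elementwise
        tab = analysis_scale(datasets.simulate_species(well_conditioned_spec,
                                                       seed=82))
        fit = mm.fit_multivariate(tab)
        ens = mm.parametric_bootstrap(fit, n_draws=60, seed=6)
        assert ens.n_failed == 0
        mc_se = ens.draws.std(axis=0, ddof=1) / np.sqrt(ens.n_draws)
        assert np.all(np.abs(ens.draws.mean(axis=0) - fit.ID) <= 3 * mc_se + 5e-3)
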