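import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mkomega import (
    GammaDFE,
    PooledData,
    SiteFrequencySpectrum,
    bootstrap_fit,
    expected_sfs,
    fit_gamma_zero,
    log_likelihood,
    mean_selection_strength,
    omega_na_from_dfe,
    pool_genes,
    relative_fixation_rate,
    sfs_class_weight,
    sojourn_density,
)
from mkomega.dfe import FitOptions, selection_kernel
from mkomega.sfs import NONSYNONYMOUS, SYNONYMOUS
from .conftest import make_gene


def simulate_pooled(
    rng, shape=0.4, mean_effect=43.09, omega_a=0.04, n=40,
    L_syn=2.5e6, L_nonsyn=7.5e6, theta=1e-3, div=0.012, distort=True,
):
    """Draw pooled spectra + divergence directly from the model."""
    kernel = selection_kernel(n)
    i = np.arange(1, n)
    r = 1 + 0.3 * np.exp(-(i - 1) / 4.0) if distort else np.ones(n - 1)
    mu_syn = L_syn * theta * r / i
    if mean_effect is None:
        phi = 1.0 / i  # neutral nonsynonymous class
        omega_na = 1.0
    else:
        phi = kernel.weights(shape, mean_effect)
        omega_na = kernel.omega_na(shape, mean_effect)
    mu_non = L_nonsyn * theta * r * phi
    return (
        PooledData(
            L_syn=L_syn, L_nonsyn=L_nonsyn,
            sfs_syn=SiteFrequencySpectrum(n, rng.poisson(mu_syn).astype(float),
                                          site_class=SYNONYMOUS),
            sfs_nonsyn=SiteFrequencySpectrum(n, rng.poisson(mu_non).astype(float),
                                             site_class=NONSYNONYMOUS),
            D_syn=float(rng.poisson(L_syn * div)),
            D_nonsyn=float(rng.poisson(L_nonsyn * div * (omega_na + omega_a))),
            n_genes=1,
        ),
        omega_na,
    )


class TestSojournDensity:
    def test_neutral_limit(self):
        assert sojourn_density(0.5, 0.0) == pytest.approx(2.0)
        assert sojourn_density(0.25, 0.0) == pytest.approx(4.0)

    def test_high_precision_oracle(self):
        # frozen 25-digit values (arbitrary-precision evaluation)
        assert sojourn_density(0.5, 50.0) == pytest.approx(
            3.999999999944448224540915, rel=1e-10
        )
        assert sojourn_density(0.5, -50.0) == pytest.approx(
            5.555177545908458243947220e-11, rel=1e-10
        )

    def test_stable_at_extreme_selection(self):
        for S in (1e5, -1e5):
            v = sojourn_density(np.array([1e-4, 0.5, 1 - 1e-4]), S)
            assert np.all(np.isfinite(v)) and np.all(v >= 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            sojourn_density(0.0, 1.0)
        with pytest.raises(ValueError):
            sojourn_density(1.0, 1.0)


class TestFixationRate:
    def test_limits_and_values(self):
        assert relative_fixation_rate(0.0) == 1.0
        assert relative_fixation_rate(-2.0) == pytest.approx(
            0.3130352854993313, rel=1e-12
        )

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-100, 100))
    def test_antisymmetry_identity(self, S):
        f = relative_fixation_rate
        assert f(S) - f(-S) == pytest.approx(S, abs=1e-8 * (1 + abs(S)))

    def test_deeply_deleterious(self):
        assert relative_fixation_rate(-800.0) == pytest.approx(0.0, abs=1e-300)
        assert relative_fixation_rate(-800.0) >= 0


class TestClassWeight:
    @pytest.mark.parametrize("n", [4, 10, 20, 40])
    def test_neutral_is_one_over_i(self, n):
        i = np.arange(1, n)
        w = sfs_class_weight(i, n, np.zeros(1))[:, 0]
        assert w == pytest.approx(1.0 / i, rel=1e-9)

    def test_frozen_arbitrary_precision_value(self):
        assert sfs_class_weight([3], 10, [-5.0])[0, 0] == pytest.approx(
            0.1289855040144784, rel=1e-10
        )

    def test_selected_below_neutral(self):
        n = 20
        i = np.arange(1, n)
        for s in (0.5, 5.0, 200.0, 2e4):
            w = sfs_class_weight(i, n, [-s])[:, 0]
            assert np.all(w < 1.0 / i)
            assert np.all(w > 0)

    def test_branches_agree_at_boundaries(self):
        # Taylor/Kummer at s = 1e-3 and Kummer/asymptotic at s = 400
        n = 30
        i = np.arange(1, n)
        for s0 in (1e-3, 400.0):
            lo = sfs_class_weight(i, n, [-(s0 * (1 - 1e-9))])[:, 0]
            hi = sfs_class_weight(i, n, [-(s0 * (1 + 1e-9))])[:, 0]
            assert lo == pytest.approx(hi, rel=1e-6)


class TestExpectedSfs:
    def test_neutral_closed_form(self):
        out = expected_sfs(4, theta=1.0, L=1.0)
        assert out == pytest.approx([1.0, 0.5, 1.0 / 3.0], rel=1e-12)

    def test_neutral_closed_form_large_n(self):
        n = 100
        r = np.linspace(0.5, 2.0, n - 1)
        out = expected_sfs(n, theta=2.5, L=3.0, r=r)
        assert out == pytest.approx(3.0 * 2.5 * r / np.arange(1, n), rel=1e-6)

    def test_selected_below_neutral(self):
        dfe = GammaDFE(0.4, 500.0)
        sel = expected_sfs(20, 1.0, 1.0, dfe=dfe)
        neu = expected_sfs(20, 1.0, 1.0)
        assert np.all(sel < neu)

    def test_monte_carlo_oracle(self):
        # independent oracle: per-draw closed-form class weights averaged
        # over raw gamma draws vs the quadrature path
        shape, mean, n = 0.5, 500.0, 20
        rng = np.random.default_rng(7)
        draws = rng.gamma(shape, mean / shape, size=300_000)
        w = sfs_class_weight(np.arange(1, n), n, -draws)
        mc = w.mean(axis=1)
        se = w.std(axis=1) / np.sqrt(len(draws))
        quad = expected_sfs(n, 1.0, 1.0, dfe=GammaDFE(shape, mean))
        assert np.all(np.abs(quad - mc) < 3 * se + 1e-9)

    def test_folded_mode(self):
        unf = expected_sfs(6, 1.3, 2.0)
        fol = expected_sfs(6, 1.3, 2.0, folded=True)
        assert fol == pytest.approx([unf[0] + unf[4], unf[1] + unf[3], unf[2]])


class TestOmegaNa:
    def test_neutral_and_strong_limits(self):
        assert omega_na_from_dfe(GammaDFE(0.4, 1e-5)) == pytest.approx(1.0, abs=1e-4)
        assert omega_na_from_dfe(GammaDFE(2.0, 1e6)) == pytest.approx(0.0, abs=1e-4)

    def test_strictly_decreasing_in_mean_effect(self):
        means = np.logspace(-3, 5, 17)
        vals = [omega_na_from_dfe(GammaDFE(0.4, m)) for m in means]
        assert np.all(np.diff(vals) < 0)
        assert all(0 < v <= 1 for v in vals)

    def test_two_independent_oracles_agree(self):
        dfe = GammaDFE(0.5, 100.0)
        quad = omega_na_from_dfe(dfe)
        rng = np.random.default_rng(11)
        s = rng.gamma(0.5, 200.0, size=2_000_000)
        mc = float(np.mean(relative_fixation_rate(-s)))
        assert quad == pytest.approx(mc, abs=1e-3)

    def test_kernel_matches_adaptive_quadrature(self):
        for shape, mean in [(0.4, 43.09), (0.2, 5.0), (1.5, 8e3)]:
            kern = selection_kernel(40).omega_na(shape, mean)
            assert kern == pytest.approx(
                omega_na_from_dfe(GammaDFE(shape, mean)), rel=1e-6
            )


class TestLikelihood:
    def _tiny_pooled(self):
        return PooledData(
            L_syn=1.0, L_nonsyn=1.0,
            sfs_syn=SiteFrequencySpectrum(4, np.array([1.0, 0, 0]), site_class=SYNONYMOUS),
            sfs_nonsyn=SiteFrequencySpectrum(4, np.zeros(3), site_class=NONSYNONYMOUS),
            D_syn=0.0, D_nonsyn=0.0, n_genes=1,
        )

    def test_poisson_unit_contribution(self):
        # observed 1 at expectation 1 contributes ln f(1;1) = -1; remaining
        # zero-count classes each contribute -expectation
        pooled = self._tiny_pooled()
        dfe = GammaDFE(0.4, 1e8)  # all nonsynonymous expectations ~ 0
        ll = log_likelihood(pooled, dfe, theta=1.0, r=np.ones(3))
        neutral_rest = 0.5 + 1.0 / 3.0
        sel = expected_sfs(4, 1.0, 1.0, dfe=dfe).sum()
        assert ll == pytest.approx(-1.0 - neutral_rest - sel, rel=1e-9)

    def test_gauge_invariance(self):
        # scaling all r by c and theta by 1/c leaves the likelihood fixed
        rng = np.random.default_rng(0)
        pooled, _ = simulate_pooled(rng, L_syn=1e5, L_nonsyn=3e5)
        dfe = GammaDFE(0.4, 50.0)
        r = np.linspace(0.8, 1.4, 39)
        a = log_likelihood(pooled, dfe, theta=1e-3, r=r)
        b = log_likelihood(pooled, dfe, theta=1e-3 / 3.0, r=3.0 * r)
        assert a == pytest.approx(b, rel=1e-12)

    def test_truth_beats_perturbation(self):
        # loglik at the generating parameters should beat a doubled mean
        # effect in nearly every replicate
        wins = 0
        reps = 100
        truth = GammaDFE(0.4, 43.09)
        worse = GammaDFE(0.4, 86.18)
        rng = np.random.default_rng(5)
        for _ in range(reps):
            pooled, _ = simulate_pooled(rng, L_syn=2e5, L_nonsyn=6e5, distort=False)
            r = np.ones(39)
            if log_likelihood(pooled, truth, 1e-3, r) > log_likelihood(
                pooled, worse, 1e-3, r
            ):
                wins += 1
        assert wins >= 95

    def test_zero_expectation_nonzero_count(self):
        pooled = self._tiny_pooled()
        with pytest.warns(RuntimeWarning, match="zero expectation"):
            ll = log_likelihood(pooled, GammaDFE(0.4, 10.0), theta=0.0, r=np.ones(3))
        assert ll == -np.inf


class TestFit:
    def test_parameter_recovery(self, fast_opts):
        rng = np.random.default_rng(21)
        pooled, omega_na_true = simulate_pooled(rng)
        fit = fit_gamma_zero(pooled, fast_opts)
        alpha_true = 0.04 / (omega_na_true + 0.04)
        assert fit.alpha == pytest.approx(alpha_true, abs=0.05)
        assert fit.dfe.shape == pytest.approx(0.4, rel=0.25)
        # the decomposition identity holds to machine precision
        assert fit.omega_a + fit.omega_na == pytest.approx(fit.dn_ds, rel=1e-14)
        assert fit.alpha * fit.dn_ds == pytest.approx(fit.omega_a, rel=1e-14)

    def test_mean_selection_strength_recovery(self, fast_opts):
        rng = np.random.default_rng(8)
        pooled, _ = simulate_pooled(rng)
        fit = fit_gamma_zero(pooled, fast_opts)
        assert mean_selection_strength(fit) == pytest.approx(43.09, rel=0.3)
        assert mean_selection_strength(fit) == fit.dfe.mean_effect

    def test_neutral_null_recovery(self, fast_opts):
        rng = np.random.default_rng(3)
        pooled, _ = simulate_pooled(rng, mean_effect=None, omega_a=0.0)
        fit = fit_gamma_zero(pooled, fast_opts)
        assert fit.alpha == pytest.approx(0.0, abs=0.05)
        assert 0 <= fit.omega_na <= 1

    def test_profiled_totals_match(self, fast_opts):
        # at the optimum the fitted expectations reproduce the observed
        # total polymorphism count (Poisson MLE closed form)
        rng = np.random.default_rng(4)
        pooled, _ = simulate_pooled(rng, L_syn=3e5, L_nonsyn=9e5)
        fit = fit_gamma_zero(pooled, fast_opts)
        e_syn = expected_sfs(40, fit.theta_syn, pooled.L_syn, r=fit.r)
        e_non = expected_sfs(40, fit.theta_syn, pooled.L_nonsyn, dfe=fit.dfe, r=fit.r)
        observed = pooled.sfs_syn.total + pooled.sfs_nonsyn.total
        assert e_syn.sum() + e_non.sum() == pytest.approx(observed, rel=1e-6)

    def test_folded_fit_recovers_alpha(self, fast_opts):
        from mkomega import fold_sfs
        from dataclasses import replace

        rng = np.random.default_rng(17)
        pooled, omega_na_true = simulate_pooled(rng)
        folded = replace(
            pooled,
            sfs_syn=fold_sfs(pooled.sfs_syn),
            sfs_nonsyn=fold_sfs(pooled.sfs_nonsyn),
        )
        fit = fit_gamma_zero(folded, fast_opts)
        alpha_true = 0.04 / (omega_na_true + 0.04)
        assert fit.folded
        assert fit.alpha == pytest.approx(alpha_true, abs=0.07)

    def test_requires_synonymous_polymorphism(self):
        pooled = PooledData(
            L_syn=10.0, L_nonsyn=30.0,
            sfs_syn=SiteFrequencySpectrum(6, np.zeros(5), site_class=SYNONYMOUS),
            sfs_nonsyn=SiteFrequencySpectrum(6, np.zeros(5), site_class=NONSYNONYMOUS),
            D_syn=1.0, D_nonsyn=1.0, n_genes=1,
        )
        with pytest.raises(ValueError, match="polymorphism"):
            fit_gamma_zero(pooled)


class TestBootstrap:
    def test_single_gene_degenerate(self, fast_opts, small_world):
        gene = max(small_world.genes, key=lambda g: g.sfs_syn.total)
        res = bootstrap_fit([gene], B=4, seed=0, opts=fast_opts)
        for rep in res.replicates:
            assert rep.omega_a == pytest.approx(res.point.omega_a, rel=1e-9)
        lo, hi = res.ci("omega_a")
        assert lo == pytest.approx(hi, rel=1e-9)

    def test_default_replicate_count(self):
        import inspect

        assert inspect.signature(bootstrap_fit).parameters["B"].default == 100

    def test_ci_shrinks_with_data(self, fast_opts, small_world):
        genes = small_world.genes
        rng = np.random.default_rng(0)
        small = [genes[j] for j in rng.choice(len(genes), 100, replace=False)]
        res_small = bootstrap_fit(small, B=30, seed=1, opts=fast_opts)
        res_big = bootstrap_fit(genes, B=30, seed=1, opts=fast_opts)
        w = lambda r: np.subtract(*reversed(r.ci("omega_na")))
        assert w(res_big) < w(res_small)
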