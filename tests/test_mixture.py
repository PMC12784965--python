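"""Poisson-NB mixture: pmf, moment estimators, alpha fit and LRT."""

import numpy as np
import pytest
from scipy.stats import poisson

import selscape as ss
from selscape.mixture import (
    estimate_m0_from_sites,
    mixture_loglik,
    nbd_pmf,
)
from selscape.simulate import simulate_site_counts


class TestEstimateM0:
    def test_synonymous_calibrated_default(self):
        m0, flags = ss.estimate_m0(10, 300.0, 100.0, 100)
        assert m0 == pytest.approx(0.3)
        assert flags == ()

    def test_zero_s_uses_cohort_fallback(self):
        m0, flags = ss.estimate_m0(0, 300.0, 100.0, 100, cohort_syn_rate=0.02)
        assert m0 == pytest.approx(0.02 * 300 / 100)
        assert "S0_cohort_fallback" in flags

    def test_zero_s_without_fallback_rejected(self):
        with pytest.raises(ValueError):
            ss.estimate_m0(0, 300.0, 100.0, 100)

    def test_synonymous_estimator_recovery_median(self, rng):
        """Median within +-20% of truth over replicate simulated genes."""
        m0, n, ratio = 0.05, 500, 3.0
        estimates = [
            ss.estimate_m0(rng.poisson(m0 * n / ratio), 3.0, 1.0, n, 0.01)[0]
            for _ in range(200)
        ]
        assert abs(np.median(estimates) / m0 - 1) < 0.2

    def test_trimmed_site_estimator_ignores_hotspots(self, rng):
        z = rng.poisson(0.1, 500)
        z[7] = 25
        m0, flags = estimate_m0_from_sites(z)
        assert m0 == pytest.approx(0.1, abs=0.05)
        assert "recurrent_sites_trimmed" in flags


class TestMixturePmf:
    def test_eta_zero_degenerates_to_poisson(self):
        z = np.arange(20)
        assert np.allclose(
            ss.mixture_pmf(z, 0.1, 5.0, 0.0, 1.51), poisson.pmf(z, 0.1)
        )

    def test_hand_evaluated_zero_class_probability(self):
        # 0.99*exp(-0.1) + 0.01*(1.51/6.51)^1.51
        assert ss.mixture_pmf(0, 0.1, 5.0, 0.01, 1.51) == pytest.approx(
            0.8968899439, abs=1e-9
        )

    def test_normalises_to_one(self):
        z = np.arange(0, 10 * 15)
        total = ss.mixture_pmf(z, 0.1, 5.0, 0.01, 1.51).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_large_alpha_collapses_nbd_to_poisson(self):
        z = np.arange(200)
        tv = 0.5 * np.abs(nbd_pmf(z, 5.0, 1e6) - poisson.pmf(z, 5.0)).sum()
        assert tv < 1e-3

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ss.mixture_pmf(-1, 0.1, 5.0, 0.01, 1.51)


def _moments(eta, m0, m1, alpha):
    """Exact mixture moments (mean, variance) of the site counts."""
    mean = (1 - eta) * m0 + eta * m1
    var = mean + eta * (1 - eta) * (m1 - m0) ** 2 + eta * m1**2 / alpha
    return mean, var


class TestMomEstimates:
    def test_printed_formula_on_reference_moments(self):
        m1, eta, _ = ss.mom_estimates(0.149, 0.552263, 0.1, 1.51)
        assert m1 == pytest.approx(5.0805, abs=1e-3)
        assert eta == pytest.approx(0.00984, abs=1e-4)

    def test_mean_at_m0_gives_no_driver_component(self):
        m1, eta, _ = ss.mom_estimates(0.2, 0.3, 0.2, 1.51)
        assert eta == 0.0 and np.isnan(m1)

    def test_degenerate_moments_truncate_eta(self):
        m1, eta, flags = ss.mom_estimates(0.2, 0.2, 0.1, 1.51)
        assert m1 == pytest.approx(0.1602, abs=1e-3)
        assert eta == 1.0
        assert "eta_truncated" in flags

    def test_exact_inversion_recovers_parameters_to_machine_precision(self):
        for eta, m0, m1, alpha in [
            (0.01, 0.1, 5.0, 1.51),
            (0.3, 0.5, 2.0, 0.8),
            (0.05, 0.2, 1.0, 3.0),
        ]:
            mean, var = _moments(eta, m0, m1, alpha)
            m1_hat, eta_hat, _ = ss.mom_estimates(mean, var, m0, alpha, mode="exact")
            assert m1_hat == pytest.approx(m1, rel=1e-9)
            assert eta_hat == pytest.approx(eta, rel=1e-9)

    @pytest.mark.parametrize("eta", [0.005, 0.02, 0.1])
    def test_printed_formula_accurate_when_m1_dominates_m0(self, eta):
        m0, alpha = 0.05, 1.51
        m1 = 25 * m0  # regime the approximation assumes
        mean, var = _moments(eta, m0, m1, alpha)
        _, eta_hat, _ = ss.mom_estimates(mean, var, m0, alpha)
        assert eta_hat == pytest.approx(eta, rel=0.05)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            ss.mom_estimates(0.2, -0.1, 0.1, 1.51)


class TestFitAlphaGlobal:
    def test_pure_poisson_cohort_falls_back_with_flag(self, rng):
        zs = [rng.poisson(0.01, 50) for _ in range(20)]
        zs = [z for z in zs if z.var() <= z.mean()] or [np.zeros(50, dtype=int)]
        alpha, flags = ss.fit_alpha_global(zs, [0.01] * len(zs))
        assert alpha == ss.DEFAULT_ALPHA
        assert "alpha_fallback" in flags

    def test_recovers_shape_with_dense_driver_signal(self, rng):
        """Shape is identifiable when genes carry many driver sites."""
        zs = [
            simulate_site_counts(rng, 500, 0.05, 0.1, 5.0, 1.5)["z"]
            for _ in range(150)
        ]
        alpha, flags = ss.fit_alpha_global(zs, [0.1] * 150)
        assert 1.2 <= alpha <= 1.9
        assert "alpha_boundary" not in flags


class TestLrt:
    def test_no_driver_component_gives_unit_p(self):
        stat, p = ss.lrt_eta(np.zeros(100), 0.1, float("nan"), 0.0, 1.51)
        assert (stat, p) == (0.0, 1.0)

    def test_single_hotspot_is_overwhelming_evidence(self, rng):
        z = rng.poisson(0.1, 500)
        z[42] = 20
        fit = ss.fit_gene_mixture("g", z, 0.1, 1.51)
        assert fit.lrt_p < 1e-4

    def test_statistic_invariant_under_codon_permutation(self, rng):
        z = simulate_site_counts(rng, 300, 0.05, 0.1, 6.0, 1.51)["z"]
        fit1 = ss.fit_gene_mixture("g", z, 0.1, 1.51)
        fit2 = ss.fit_gene_mixture("g", rng.permutation(z), 0.1, 1.51)
        assert fit1.lrt_stat == pytest.approx(fit2.lrt_stat, rel=1e-12)

    def test_boundary_lrt_calibration_with_known_m0(self, rng):
        """Null rejection rate at nominal 5%: in [0.03, 0.07] or below."""
        rej = 0
        n_rep = 500
        for _ in range(n_rep):
            z = rng.poisson(0.1, 500)
            fit = ss.fit_gene_mixture("g", z, 0.1, 1.51)
            rej += fit.lrt_p < 0.05
        assert rej / n_rep <= 0.07

    def test_chi2_2_mode_is_more_conservative(self, rng):
        z = rng.poisson(0.1, 500)
        z[0] = 6
        a = ss.fit_gene_mixture("g", z, 0.1, 1.51, lrt_df_mode="half1")
        b = ss.fit_gene_mixture("g", z, 0.1, 1.51, lrt_df_mode="chi2_2")
        assert b.lrt_p >= a.lrt_p


def test_fit_gene_mixture_loglik_consistency(rng):
    z = simulate_site_counts(rng, 200, 0.05, 0.1, 6.0, 1.51)["z"]
    fit = ss.fit_gene_mixture("g", z, 0.1, 1.51)
    if fit.eta > 0:
        assert fit.loglik == pytest.approx(
            mixture_loglik(z, fit.m0, fit.m1, fit.eta, fit.alpha)
        )
        assert fit.beta == pytest.approx(fit.alpha / (fit.m1 - fit.m0))
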