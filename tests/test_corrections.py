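import numpy as np
import pandas as pd
import pytest

from fretkit.corrections import (CorrectionSet, EstimationError, accurate_E_S,
                                 alpha_from_donor_only, apparent_E, apparent_S,
                                 background_correct, beta_gamma_global,
                                 delta_from_acceptor_only, efficiency_uncertainty,
                                 fret_signal, gamma_from_static_line,
                                 population_center_ES)


class TestApparent:
    @pytest.mark.parametrize("ad, dd, expected", [(80, 20, 0.8), (0, 50, 0.0),
                                                  (33, 67, 0.33)])
    def test_apparent_e(self, ad, dd, expected):
        assert apparent_E(dd, ad) == pytest.approx(expected)

    def test_zero_denominator_flagged_nan(self):
        assert np.isnan(apparent_E(0, 0))
        assert np.isnan(apparent_S(0, 0, 0))


class TestBackgroundCorrect:
    def test_zero_rates_identity(self):
        c = background_correct({"DemDex": 10, "AemDex": 20, "AemAex": 30}, {}, 1e-3)
        assert c == {"DemDex": 10.0, "AemDex": 20.0, "AemAex": 30.0}

    def test_rate_times_duration(self):
        c = background_correct({"DemDex": 100, "AemDex": 1, "AemAex": 5},
                               {"DemDex": 2000.0, "AemDex": 2000.0}, 1e-3)
        assert c["DemDex"] == pytest.approx(98.0)
        assert c["AemDex"] == pytest.approx(-1.0)  # negative allowed, carries noise info


class TestAlphaDelta:
    @staticmethod
    def synthetic_table(n, aem, dem, aex, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "ii_dem_dex": rng.poisson(dem, n).astype(float),
            "ii_aem_dex": rng.poisson(aem, n).astype(float),
            "ii_aem_aex": rng.poisson(aex, n).astype(float),
        })

    def test_alpha_algebraic_inversion(self):
        # donor-only E center 0.0476 -> alpha = 0.05
        t = self.synthetic_table(4000, aem=0.0476 * 42, dem=(1 - 0.0476) * 42, aex=0.2)
        assert alpha_from_donor_only(t) == pytest.approx(0.05, abs=0.003)

    def test_delta_algebraic_inversion(self):
        # acceptor-only S center 0.107 -> delta = 0.12
        t = self.synthetic_table(4000, aem=0.107 * 40, dem=0.0, aex=(1 - 0.107) * 40)
        assert delta_from_acceptor_only(t) == pytest.approx(0.12, abs=0.006)

    def test_too_few_bursts(self):
        t = self.synthetic_table(50, aem=2, dem=40, aex=0.2)
        with pytest.raises(EstimationError, match="donor-only"):
            alpha_from_donor_only(t)


class TestBetaGamma:
    def test_synthetic_centers_exact(self):
        beta_t, gamma_t = 1.6, 0.4
        e_pr = np.array([0.15, 0.5])
        inv_s = (1 + beta_t * gamma_t) + beta_t * (1 - gamma_t) * e_pr
        centers = list(zip(e_pr, 1.0 / inv_s))
        beta, gamma, diag = beta_gamma_global(centers)
        assert beta == pytest.approx(beta_t, abs=1e-12)
        assert gamma == pytest.approx(gamma_t, abs=1e-12)

    def test_ideal_dyes_flat_line(self):
        centers = [(0.2, 0.5), (0.7, 0.5)]  # 1/S = 2 for all E
        beta, gamma, diag = beta_gamma_global(centers)
        assert beta == pytest.approx(1.0, abs=1e-9)
        assert gamma == pytest.approx(1.0, abs=1e-9)

    def test_single_population_error(self):
        with pytest.raises(ValueError, match="lifetime route"):
            beta_gamma_global([(0.5, 0.5)])

    def test_close_populations_warn(self):
        with pytest.warns(UserWarning, match="ill-conditioned"):
            beta_gamma_global([(0.50, 0.52), (0.55, 0.50)])


class TestAccurateES:
    def test_fret_signal_arithmetic(self):
        assert fret_signal(100, 100, 50, 0.05, 0.12) == pytest.approx(89.0)

    def test_all_crosstalk_burst(self):
        # AemDex = alpha * DemDex exactly -> F_A|D = -delta * AemAex
        assert fret_signal(5.0, 100.0, 50.0, 0.05, 0.12) == pytest.approx(-6.0)

    def test_e_s_arithmetic(self):
        cs = CorrectionSet(alpha=0.05, beta=1.6, gamma=0.4, delta=0.12)
        e, s = accurate_E_S(100.0, 100.0, 50.0, cs)
        assert e == pytest.approx(89.0 / 129.0, abs=1e-9)     # 0.6899
        assert s == pytest.approx(129.0 / 160.25, abs=1e-9)   # 0.805

    def test_identity_when_ideal(self):
        cs = CorrectionSet.ideal()
        e, _ = accurate_E_S(30.0, 70.0, 50.0, cs)
        assert e == pytest.approx(apparent_E(30, 70))

    def test_beta_consistency(self):
        """E is invariant under rescaling all Aex counts together with beta."""
        cs1 = CorrectionSet(alpha=0.05, beta=1.6, gamma=0.4, delta=0.12)
        cs2 = CorrectionSet(alpha=0.05, beta=1.6 * 2.5, gamma=0.4, delta=0.12)
        e1, _ = accurate_E_S(100.0, 80.0, 50.0, cs1)
        # delta subtracts delta*AemAex from the FRET signal: rescale delta too
        cs2b = CorrectionSet(alpha=0.05, beta=1.6 * 2.5, gamma=0.4, delta=0.12 / 2.5)
        e2, _ = accurate_E_S(100.0, 80.0, 50.0 * 2.5, cs2b)
        assert e1 == pytest.approx(e2, abs=1e-12)


class TestEfficiencyUncertainty:
    @pytest.mark.parametrize("e, expected", [(0.0, 0.0), (1.0, 0.0),
                                             (0.49, 0.0575), (0.92, 0.0169)])
    def test_values(self, e, expected):
        assert efficiency_uncertainty(e, 1.0, 0.23) == pytest.approx(expected, abs=5e-4)

    def test_maximal_at_half_and_symmetric(self):
        e = np.linspace(0.01, 0.99, 99)
        de = efficiency_uncertainty(e, 0.4, 0.092)
        assert np.argmax(de) == np.argmin(np.abs(e - 0.5))
        np.testing.assert_allclose(de, de[::-1], atol=1e-12)


class TestGammaStaticLine:
    def test_exact_inversion(self):
        # population at E=0.5 with gamma 0.4: E_PR = 0.4*0.5/(0.5+0.2) = 0.2857
        e_pr = 0.4 * 0.5 / (0.5 + 0.4 * 0.5)
        gamma, notes = gamma_from_static_line(e_pr, 2.0, 4.0)
        assert gamma == pytest.approx(0.4, abs=1e-9)
        assert notes == []

    def test_ideal_returns_one(self):
        gamma, _ = gamma_from_static_line(0.5, 2.0, 4.0)
        assert gamma == pytest.approx(1.0, abs=1e-9)


class TestFlatS:
    def test_s_independent_of_e(self, static_mixture_run):
        """After beta/gamma correction, double-labeled molecules have S ~ 0.5
        regardless of E (the basis of the global regression)."""
        truth_cs = static_mixture_run["truth"].corrections
        _, s = population_center_ES(static_mixture_run["fret"], truth_cs)
        assert s == pytest.approx(0.5, abs=0.02)
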