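import numpy as np
import pytest
from scipy import stats

from fretkit.photon_data import DEX, assign_excitation
from fretkit.simulate import (DyePhysics, FretState, KineticModel, SimConfig,
                              implied_corrections, relaxation_times, simulate_bursts,
                              simulate_polarized_decays, three_state_chain)
from fretkit.anisotropy import anisotropy_decay, fit_anisotropy

IDEAL = DyePhysics(phi_d=1.0, phi_a=1.0, g_d=1.0, g_a=1.0, crosstalk=0.0,
                   direct_excitation=0.0, tau_d0_ns=4.0)


class TestImpliedCorrections:
    def test_gamma_is_detection_qy_ratio(self):
        dyes = DyePhysics(phi_d=0.72, phi_a=0.32, g_d=1.0, g_a=1.0, crosstalk=0.0,
                         direct_excitation=0.0)
        cs = implied_corrections(SimConfig(n_bursts=1, dyes=dyes))
        assert cs.gamma == pytest.approx(0.32 / 0.72, abs=1e-6)  # 0.4444

    def test_zero_crosstalk_gives_zero_alpha(self):
        cs = implied_corrections(SimConfig(n_bursts=1, dyes=IDEAL))
        assert cs.alpha == 0.0
        assert cs.delta == 0.0

    def test_ideal_symmetric_dyes(self):
        cfg = SimConfig(n_bursts=1, dyes=IDEAL, excitation_ratio=1.0)
        cs = implied_corrections(cfg)
        assert cs.gamma == 1.0
        assert cs.beta == pytest.approx(1.0)  # equal windows, equal fluxes

    def test_consensus_defaults(self):
        cs = implied_corrections(SimConfig(n_bursts=1))
        assert cs.alpha == pytest.approx(0.05, abs=1e-9)
        assert cs.beta == pytest.approx(1.6, abs=1e-9)
        assert cs.gamma == pytest.approx(0.40, abs=1e-9)
        assert cs.delta == pytest.approx(0.12, abs=1e-9)


class TestSimulateBursts:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_bursts=50, seed=9)
        s1, _ = simulate_bursts(cfg)
        s2, _ = simulate_bursts(cfg)
        np.testing.assert_array_equal(s1.macrotimes, s2.macrotimes)
        np.testing.assert_array_equal(s1.detectors, s2.detectors)
        np.testing.assert_array_equal(s1.microtimes, s2.microtimes)

    def test_zero_state_model_rejected(self):
        with pytest.raises(ValueError):
            KineticModel(states=())

    def test_static_e_app_unbiased(self):
        """Ideal dyes, single state E=0.5: burst E_app is Binomial(N, 0.5)."""
        cfg = SimConfig(n_bursts=10000, seed=11, dyes=IDEAL, fractions=(1.0, 0, 0),
                        bg_donor_hz=0.0, bg_acceptor_hz=0.0,
                        kinetics=KineticModel.static(efficiency=0.5))
        stream, truth = simulate_bursts(cfg)
        stream = assign_excitation(stream, cfg.scheme())
        band = stream.band()
        t = stream.times_s
        dex = stream.excitation == DEX
        n_tot = a_tot = 0
        ks, ns = [], []
        for _, r in truth.bursts.iterrows():
            i0, i1 = np.searchsorted(t, [r.start_s - 1e-9, r.stop_s + 1e-9])
            sel = dex[i0:i1]
            k = int(np.sum(sel & (band[i0:i1] == 1)))
            n = int(np.sum(sel))
            if n >= 10:
                ks.append(k)
                ns.append(n)
            a_tot += k
            n_tot += n
        # unbiasedness within 3 binomial standard errors
        p = a_tot / n_tot
        se = np.sqrt(0.25 / n_tot)
        assert abs(p - 0.5) < 3 * se
        # per-burst goodness of fit: the randomized PIT of k ~ Binomial(n, 0.5)
        # is exactly Uniform(0,1) under the null (handles the discreteness)
        ks_a, ns_a = np.array(ks), np.array(ns)
        rng = np.random.default_rng(99)
        u = (stats.binom.cdf(ks_a - 1, ns_a, 0.5)
             + rng.uniform(size=ks_a.size) * stats.binom.pmf(ks_a, ns_a, 0.5))
        _, pval = stats.kstest(u, "uniform")
        assert pval > 0.01

    def test_two_state_symmetric_occupancy(self):
        kin = KineticModel.two_state(FretState(efficiency=0.3), FretState(efficiency=0.7),
                                     k12=2000.0, k21=2000.0)
        cfg = SimConfig(n_bursts=2000, seed=12, dyes=IDEAL, fractions=(1.0, 0, 0),
                        kinetics=kin)
        _, truth = simulate_bursts(cfg)
        occ = truth.bursts["occ_state0"].to_numpy()
        se = occ.std() / np.sqrt(occ.size)
        assert abs(occ.mean() - 0.5) < 4 * se

    def test_donor_microtime_mean(self):
        """State E=0.75, tau_D(0)=4 ns: donor microtimes average IRF mean + 1 ns."""
        cfg = SimConfig(n_bursts=800, seed=13, dyes=IDEAL, fractions=(1.0, 0, 0),
                        bg_donor_hz=0.0, bg_acceptor_hz=0.0,
                        kinetics=KineticModel.static(efficiency=0.75))
        stream, _ = simulate_bursts(cfg)
        stream = assign_excitation(stream, cfg.scheme())
        donor = (stream.band() == 0) & (stream.excitation == DEX)
        mt_ns = stream.microtimes[donor] * stream.microtime_resolution_ps * 1e-3
        expected = cfg.dyes.irf_mean_ns + 4.0 * (1 - 0.75)
        assert mt_ns.mean() == pytest.approx(expected, abs=0.05)

    def test_dwells_tile_bursts(self):
        kin = KineticModel.two_state(FretState(efficiency=0.3), FretState(efficiency=0.7),
                                     k12=500.0, k21=800.0)
        cfg = SimConfig(n_bursts=300, seed=14, dyes=IDEAL, fractions=(1.0, 0, 0),
                        kinetics=kin)
        _, truth = simulate_bursts(cfg)
        for bid, grp in truth.dwells.groupby("burst_id"):
            dur = truth.bursts.loc[truth.bursts.burst_id == bid, "duration_ms"].iloc[0] * 1e-3
            assert grp["t_start_s"].iloc[0] == 0.0
            assert grp["t_stop_s"].iloc[-1] == pytest.approx(dur, rel=1e-9)
            np.testing.assert_allclose(grp["t_stop_s"].to_numpy()[:-1],
                                       grp["t_start_s"].to_numpy()[1:], rtol=1e-12)


class TestThreeStateChain:
    def test_eigen_relaxations_exact(self):
        kin = three_state_chain(9e-6, 300e-6)
        times = relaxation_times(kin)
        np.testing.assert_allclose(times, [9e-6, 3e-4], rtol=1e-6)


class TestPolarizedDecays:
    def test_frozen_dye_constant_anisotropy(self):
        d = simulate_polarized_decays(r0=0.38, rho_ns=[1.0], amplitudes=[0.0],
                                      r_inf=0.38, n_photons=200000, seed=5)
        t, r, _ = anisotropy_decay(d)
        ok = np.isfinite(r) & (t < 10)
        assert np.nanmean(r[ok]) == pytest.approx(0.38, abs=0.01)

    def test_single_rho_recovered(self):
        d = simulate_polarized_decays(r0=0.38, rho_ns=[2.0], amplitudes=[0.38],
                                      r_inf=0.0, n_photons=1_000_000, seed=6)
        fit = fit_anisotropy(d, n_components=1)
        assert fit.rho_ns[0] == pytest.approx(2.0, rel=0.10)
        assert fit.r_inf < 0.02

    def test_biexponential_t0_limit(self):
        d = simulate_polarized_decays(r0=0.38, rho_ns=[0.5, 5.0], amplitudes=[0.2, 0.18],
                                      r_inf=0.0, n_photons=2_000_000, seed=7)
        t, r, _ = anisotropy_decay(d)
        # reconstruction matches the biexponential model bin by bin, and the
        # model itself starts at r0 at t = 0
        model = 0.2 * np.exp(-t / 0.5) + 0.18 * np.exp(-t / 5.0)
        early = np.isfinite(r) & (t < 3.0)
        assert np.nanmax(np.abs(r[early] - model[early])) < 0.03
        assert model[0] == pytest.approx(0.38, abs=0.01)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            simulate_polarized_decays(r0=0.38, rho_ns=[1.0], amplitudes=[-0.1],
                                      r_inf=0.48, n_photons=100, seed=0)
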