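import numpy as np
import pytest
from scipy.integrate import quad

from fretkit.dynamics.bva import bva, bva_expected_sigma, clipped_center_2d
from fretkit.dynamics.etau import (burst_lifetime, burst_lifetimes, dynamic_fret_line,
                                   dynamic_shift_etau, estimate_delta_R,
                                   static_fret_line, two_state_observables)
from fretkit.simulate import forster_efficiency


class TestBVAExpectedSigma:
    @pytest.mark.parametrize("e", [0.0, 1.0])
    def test_boundaries_zero(self, e):
        assert bva_expected_sigma(e, 5) == 0.0

    def test_half_at_five(self):
        assert bva_expected_sigma(0.5, 5) == pytest.approx(0.2236, abs=1e-4)

    def test_monotone_in_n(self):
        sig = [bva_expected_sigma(0.5, n) for n in (2, 5, 20, 100, 10000)]
        assert np.all(np.diff(sig) < 0)
        assert sig[-1] < 0.006


class TestBVA:
    def test_static_null_semicircle(self, static_linker_run):
        """Static molecules: bin-averaged window SDs follow the shot-noise
        semicircle and the population dynamic shift is consistent with zero
        (the magnitude of a dsDNA-like static reference)."""
        res = bva(static_linker_run["stream"], static_linker_run["fret"], n=5)
        assert abs(res.ds) < 0.015
        # Monte-Carlo null band for the populated bins
        rng = np.random.default_rng(7)
        per = res.per_burst
        for b, c in zip(res.bin_sigma, res.bin_centers):
            if not np.isfinite(b):
                continue
            sel = per[np.abs(per.e_app - c) <= 0.025]
            if len(sel) < 30:
                continue
            # forward-simulate the same statistic: binomial windows at E = c
            sims = []
            n_win = sel.n_windows.to_numpy()
            for _ in range(200):
                draws = [np.std(rng.binomial(5, c, m) / 5, ddof=1) for m in n_win[:200]]
                sims.append(np.mean(draws))
            lo, hi = np.percentile(sims, [0.5, 99.5])
            assert lo - 0.01 <= b <= hi + 0.01

    def test_two_state_positive_shift(self, two_state_run, static_linker_run):
        dyn = bva(two_state_run["stream"], two_state_run["fret"], n=5)
        stat = bva(static_linker_run["stream"], static_linker_run["fret"], n=5)
        assert dyn.ds > 0.02
        assert dyn.ds > stat.ds + 0.02

    def test_short_bursts_excluded(self, static_linker_run):
        res = bva(static_linker_run["stream"], static_linker_run["fret"].head(50), n=40)
        assert res.n_excluded > 0


class TestBurstLifetime:
    def test_mle_recovers_tau(self):
        rng = np.random.default_rng(0)
        t = 2.0 + rng.exponential(2.0, 10000)
        est = burst_lifetime(t, 2.0, 50.0)
        assert est == pytest.approx(2.0, abs=0.05)

    def test_no_fret_limit(self):
        """tau = tau_D(0) means E = 0 on the static line."""
        line = static_fret_line(4.0, 0.0, 65.0)
        assert line(4.0) == pytest.approx(0.0, abs=1e-12)
        assert line(0.0) == pytest.approx(1.0, abs=1e-12)

    def test_background_term_limits_bias(self):
        rng = np.random.default_rng(1)
        sig = 2.0 + rng.exponential(2.0, 5000)
        bg = rng.uniform(2.0, 50.0, 5000)  # 50% flat contamination
        t = np.concatenate([sig, bg])
        est = burst_lifetime(t, 2.0, 50.0, bg_fraction=0.5)
        assert est == pytest.approx(2.0, rel=0.05)

    def test_too_few_photons_nan(self):
        assert np.isnan(burst_lifetime(np.array([3.0, 4.0]), 2.0, 50.0))


class TestStaticLine:
    def test_zero_linker_is_straight(self):
        line = static_fret_line(4.0, 0.0, 65.0)
        assert line(1.0) == pytest.approx(0.75)

    def test_linker_curve_matches_quadrature(self):
        """The sampled curve agrees with direct numerical integration and
        lies above the straight line at intermediate lifetimes."""
        tau0, sigma, r0 = 4.0, 6.0, 65.0
        line = static_fret_line(tau0, sigma, r0)

        def curve_point(rc):
            norm = quad(lambda r: np.exp(-(r - rc) ** 2 / (2 * sigma**2)), 1.0, rc + 8 * sigma)[0]
            e_sp = quad(lambda r: np.exp(-(r - rc) ** 2 / (2 * sigma**2))
                        * forster_efficiency(r, r0), 1.0, rc + 8 * sigma)[0] / norm
            t1 = quad(lambda r: np.exp(-(r - rc) ** 2 / (2 * sigma**2))
                      * tau0 * (1 - forster_efficiency(r, r0)), 1.0, rc + 8 * sigma)[0] / norm
            t2 = quad(lambda r: np.exp(-(r - rc) ** 2 / (2 * sigma**2))
                      * (tau0 * (1 - forster_efficiency(r, r0))) ** 2, 1.0, rc + 8 * sigma)[0] / norm
            return t2 / t1, e_sp

        for rc in (50.0, 65.0, 80.0):
            tau_f, e_sp = curve_point(rc)
            assert line(tau_f) == pytest.approx(e_sp, abs=1e-4)
            ideal = 1 - tau_f / tau0
            assert e_sp > ideal  # curved line lies above the straight one

    def test_cubic_approximation_close(self):
        line = static_fret_line(4.0, 6.0, 65.0)
        mid = (line.tau > 0.5) & (line.tau < 3.5)
        approx = np.polyval(line.poly, line.tau[mid])
        assert np.max(np.abs(approx - line.e[mid])) < 0.01


class TestDynamicLine:
    def test_endpoints(self):
        tau, e, curve = dynamic_fret_line(0.2, 0.8, 4.0)
        assert curve(4.0 * 0.8) == pytest.approx(0.2, abs=1e-12)
        assert curve(4.0 * 0.2) == pytest.approx(0.8, abs=1e-12)

    def test_equal_occupancy_mixing_point(self):
        """Closed-form mixing: E1=0.2, E2=0.8 at equal occupancy gives
        (<tau>_F, E) = (2.72 ns, 0.5) and the curve passes through it."""
        _, _, curve = dynamic_fret_line(0.2, 0.8, 4.0)
        w1, w2 = 0.8, 0.2  # donor photon weights = 1 - E
        tau_f = (w1 * 4 * 0.8 + w2 * 4 * 0.2) / (w1 + w2)
        assert tau_f == pytest.approx(2.72)
        assert curve(tau_f) == pytest.approx(0.5, abs=1e-12)

    def test_domain_error(self):
        _, _, curve = dynamic_fret_line(0.2, 0.8, 4.0)
        with pytest.raises(ValueError):
            curve(3.9)


class TestDynamicShift:
    def test_static_null(self, static_linker_run):
        run = static_linker_run
        taus = burst_lifetimes(run["stream"], run["fret"], 4.0,
                               run["bg"].rates_hz["DemDex"])
        ok = np.isfinite(taus)
        line = static_fret_line(4.0, 6.0, 65.0)
        tc, ec = clipped_center_2d(taus[ok], run["fret"]["e_pr"].to_numpy()[ok])
        ds = dynamic_shift_etau(tc, ec, line)
        assert abs(ds) < 0.01

    def test_two_state_shift_matches_mixing(self, two_state_run):
        """The dynamic population center falls on the two-state mixing curve
        and its shift from the static line equals the curve offset there."""
        run = two_state_run
        taus = burst_lifetimes(run["stream"], run["fret"], 4.0,
                               run["bg"].rates_hz["DemDex"])
        ok = np.isfinite(taus)
        line = static_fret_line(4.0, 0.0, 65.0)
        tc, ec = clipped_center_2d(taus[ok], run["fret"]["e_pr"].to_numpy()[ok])
        _, _, curve = dynamic_fret_line(0.2, 0.8, 4.0)
        assert ec == pytest.approx(curve(tc), abs=0.03)  # on the dynamic line
        ds = dynamic_shift_etau(tc, ec, line)
        expected_ds = curve(tc) - line(tc)
        assert ds > 0.05
        assert ds == pytest.approx(expected_ds, abs=0.03)

    def test_ideal_line_example(self):
        line = static_fret_line(4.0, 0.0, 65.0)
        assert dynamic_shift_etau(2.72, 0.5, line) == pytest.approx(0.18)


class TestDeltaR:
    def test_zero_shift_zero_amplitude(self):
        est = estimate_delta_R(0.0, 65.0, 65.0, 4.0)
        assert est.delta_r == 0.0

    def test_forward_inverse_consistency(self):
        line = static_fret_line(4.0, 0.0, 65.0)
        tau_f, e_obs = two_state_observables(65.0, 5.0, 65.0, 4.0)
        ds = e_obs - line(tau_f)
        est = estimate_delta_R(ds, 65.0, 65.0, 4.0)
        assert est.delta_r == pytest.approx(5.0, abs=1e-3)

    def test_monotone_in_shift(self):
        line = static_fret_line(4.0, 0.0, 65.0)
        ds_grid = [0.002, 0.01, 0.03, 0.06, 0.1]
        drs = [estimate_delta_R(ds, 65.0, 65.0, 4.0).delta_r for ds in ds_grid]
        assert np.all(np.diff(drs) > 0)
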