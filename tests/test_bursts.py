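import numpy as np
import pandas as pd
import pytest

from fretkit.photon_data import ChannelMap, PhotonStream, assign_excitation
from fretkit.bursts import (BackgroundModel, SelectionThresholds, burst_summary,
                            estimate_background, search_bursts, select_bursts)
from fretkit.simulate import SimConfig, KineticModel, simulate_bursts


def _analyze(cfg):
    stream, truth = simulate_bursts(cfg)
    stream = assign_excitation(stream, cfg.scheme())
    bg = estimate_background(stream)
    return stream, truth, bg, search_bursts(stream, bg)


def poisson_stream(rate_hz, duration_s, seed, detector=0):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration_s)
    t = np.sort(rng.uniform(0, duration_s, n))
    macro = np.floor(t * 80e6).astype(np.int64)
    s = PhotonStream(macrotimes=macro, clock_rate=80e6,
                     detectors=np.full(n, detector, dtype=np.int16),
                     channel_map=ChannelMap.simple())
    scheme = SimConfig(n_bursts=1).scheme()
    return assign_excitation(s, scheme)


class TestBackground:
    def test_pure_poisson_rate_recovered(self):
        s = poisson_stream(2000.0, 60.0, seed=1)
        bg = estimate_background(s)
        # donor-channel Dex rate: 2 kHz x 45% duty
        assert bg.rates_hz["DemDex"] == pytest.approx(2000.0 * 0.45, rel=0.05)

    def test_empty_channel_warns_and_zero(self):
        s = poisson_stream(500.0, 10.0, seed=2, detector=0)  # no acceptor photons
        with pytest.warns(UserWarning, match="background set to 0"):
            bg = estimate_background(s)
        assert bg.rates_hz["AemAex"] == 0.0

    def test_background_with_bursts_within_10pct(self, static_mixture_run):
        bg = static_mixture_run["bg"]
        cfg = static_mixture_run["cfg"]
        assert bg.rates_hz["DemDex"] == pytest.approx(cfg.bg_donor_hz * cfg.dex_duty,
                                                      rel=0.10)
        assert bg.rates_hz["AemAex"] == pytest.approx(cfg.bg_acceptor_hz * cfg.aex_duty,
                                                      rel=0.10)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            BackgroundModel({"DemDex": -1.0})


class TestBurstSearch:
    def test_single_cluster_found(self):
        # one 60-photon cluster at 50 kHz in an otherwise sparse trace
        rng = np.random.default_rng(3)
        cluster = 0.5 + np.sort(rng.uniform(0, 60 / 50e3, 60))
        sparse = np.sort(rng.uniform(0, 1.0, 20))
        t = np.sort(np.concatenate([cluster, sparse]))
        macro = np.floor(t * 80e6).astype(np.int64)
        s = PhotonStream(macrotimes=macro, clock_rate=80e6,
                         detectors=np.ones(t.size, np.int16),  # acceptor channel
                         channel_map=ChannelMap.simple())
        s = assign_excitation(s, SimConfig(n_bursts=1).scheme())
        bg = BackgroundModel({"DemDex": 10.0, "AemDex": 5.0, "AemAex": 5.0})
        bursts = search_bursts(s, bg)
        assert len(bursts) == 1
        tot = bursts.iloc[0][["i_dem_dex", "i_aem_dex", "i_aem_aex"]].sum()
        # ~10% of the cluster falls between the alternation windows
        assert 45 <= tot <= 61

    def test_pure_background_false_positive_rate(self):
        s = poisson_stream(2000.0, 120.0, seed=4)
        bg = estimate_background(s)
        bursts = search_bursts(s, bg)
        # fewer than 1 false burst per 1e5 photons at the default settings
        assert len(bursts) <= max(1, s.n_photons // 100000)

    def test_parameter_validation(self, static_mixture_run):
        with pytest.raises(ValueError, match="m must be"):
            search_bursts(static_mixture_run["stream"], static_mixture_run["bg"], m=1)

    def test_recovery_and_boundaries(self, static_mixture_run):
        """>= 95% of bright bursts recovered with boundary error <= m photons."""
        truth = static_mixture_run["truth"].bursts
        bursts = static_mixture_run["bursts"]
        bright = truth[truth.n_photons >= 50]
        m_phot = 10
        t = static_mixture_run["stream"].times_s
        # max boundary slack: m photons at the in-burst rate, plus window padding
        found = 0
        for _, r in bright.iterrows():
            cand = bursts[(bursts.stop_s > r.start_s) & (bursts.start_s < r.stop_s)]
            if len(cand) == 0:
                continue
            c = cand.iloc[0]
            i0 = np.searchsorted(t, [c.start_s, r.start_s])
            i1 = np.searchsorted(t, [r.stop_s, c.stop_s])
            if abs(i0[1] - i0[0]) <= m_phot and abs(i1[1] - i1[0]) <= m_phot:
                found += 1
        assert found / len(bright) >= 0.95

    def test_translation_invariance(self, static_mixture_run):
        s = static_mixture_run["stream"]
        bg = static_mixture_run["bg"]
        shift_ticks = 80000 * 13  # integer number of alternation periods
        import dataclasses

        s2 = dataclasses.replace(s, macrotimes=s.macrotimes + shift_ticks,
                                 meta=dict(s.meta))
        b1 = search_bursts(s, bg)
        b2 = search_bursts(s2, bg)
        assert len(b1) == len(b2)
        np.testing.assert_allclose(b2.start_s.to_numpy(),
                                   b1.start_s.to_numpy() + shift_ticks / s.clock_rate,
                                   rtol=0, atol=1e-9)
        np.testing.assert_array_equal(b1.i_aem_dex, b2.i_aem_dex)


class TestSelection:
    def test_partition_disjoint(self, static_mixture_run):
        fret, donly, aonly = (static_mixture_run["fret"], static_mixture_run["donor_only"],
                              static_mixture_run["acceptor_only"])
        ids = [set(x.burst_id) for x in (fret, donly, aonly)]
        assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])

    def test_mixture_fractions_recovered(self, static_mixture_run):
        """70/20/10 DA / D-only / A-only mixture within +/- 3% absolute.

        Species-dependent brightness makes the detected composition differ
        from the simulated one; compare against the ground-truth composition
        of the *detected* bursts.
        """
        truth = static_mixture_run["truth"].bursts
        bursts = static_mixture_run["bursts"]
        fret, donly, aonly = (static_mixture_run["fret"], static_mixture_run["donor_only"],
                              static_mixture_run["acceptor_only"])
        # ground truth species of each detected burst (by time overlap)
        starts = truth.start_s.to_numpy()
        ix = np.searchsorted(starts, bursts.start_s.to_numpy(), side="right") - 1
        true_species = truth.species.to_numpy()[np.clip(ix, 0, len(truth) - 1)]
        det_frac = pd.Series(true_species).value_counts(normalize=True)
        n = len(bursts)
        assert len(fret) / n == pytest.approx(det_frac.get("DA", 0), abs=0.03)
        assert len(donly) / n == pytest.approx(det_frac.get("D-only", 0), abs=0.03)
        assert len(aonly) / n == pytest.approx(det_frac.get("A-only", 0), abs=0.03)

    def test_overlapping_thresholds_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SelectionThresholds(donor_only_min_s=0.5, fret_s_range=(0.25, 0.75))


class TestSummary:
    def test_identical_bursts_zero_sd(self):
        df = pd.DataFrame({"burst_id": [0, 1], "duration_ms": [1.0, 1.0],
                           "i_dem_dex": [30, 30], "i_aem_dex": [30, 30],
                           "i_aem_aex": [40, 40]})
        s = burst_summary(df)
        assert s.sd_photons == 0.0 and s.sd_duration_ms == 0.0

    def test_constant_brightness_correlation(self):
        """With (near-)constant molecular brightness, photons track duration."""
        cfg = SimConfig(n_bursts=1200, seed=21, fractions=(1.0, 0.0, 0.0),
                        brightness_mean_khz=60.0, brightness_sd_khz=1.0,
                        kinetics=KineticModel.static(efficiency=0.5))
        _, truth = simulate_bursts(cfg)
        tb = truth.bursts
        df = pd.DataFrame({"burst_id": tb.burst_id, "duration_ms": tb.duration_ms,
                           "i_dem_dex": tb.n_photons, "i_aem_dex": 0, "i_aem_aex": 0})
        s = burst_summary(df)
        assert s.corr_photons_duration > 0.9

    def test_fixed_photon_budget_anticorrelation(self):
        rng = np.random.default_rng(5)
        dur = rng.uniform(0.5, 3.0, 500)
        n = 90  # same photons regardless of duration
        df = pd.DataFrame({"burst_id": np.arange(500), "duration_ms": dur,
                           "i_dem_dex": np.full(500, n // 3),
                           "i_aem_dex": np.full(500, n // 3),
                           "i_aem_aex": np.full(500, n // 3)})
        s = burst_summary(df)
        assert s.corr_rate_duration < 0
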