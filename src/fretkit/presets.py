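"""Canned experiment configurations and drivers.

These bundle the simulation conditions and analysis settings for the
package's benchmark scenarios: correction-factor recovery on a two-state
calibration pair, slow two-state exchange quantified by dynamic PDA, and
two-timescale exchange quantified by filtered FCS.  Each driver runs the
complete pipeline from raw photon streams and returns the recovered
quantities together with the ground truth.  All randomness derives from
the seed argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .photon_data import DEX, assign_excitation
from .simulate import (DyePhysics, FretState, KineticModel, SimConfig,
                       implied_corrections, simulate_bursts, three_state_chain)
from .bursts import estimate_background, search_bursts, select_bursts
from .corrections import CorrectionSet, population_center_ES
from .pipeline import derive_corrections

__all__ = [
    "calibration_pair_configs",
    "run_correction_recovery",
    "pda_slow_exchange_config",
    "run_pda_relaxation",
    "fcs_two_timescale_config",
    "run_fcs_relaxation",
    "IDEAL_DYES",
]

#: dye physics with unit quantum yields / detection and no crosstalk or
#: direct excitation — used where the benchmark targets kinetics, not
#: photophysical corrections
IDEAL_DYES = DyePhysics(phi_d=1.0, phi_a=1.0, g_d=1.0, g_a=1.0, crosstalk=0.0,
                        direct_excitation=0.0, tau_d0_ns=3.8)


def calibration_pair_configs(seed: int, n_bursts: int = 10000,
                             e_true=(0.3, 0.7)) -> list[SimConfig]:
    """Two static measurements with distinct efficiencies and the consensus
    dye physics (alpha 0.05, beta 1.6, gamma 0.40, delta 0.12 implied)."""
    return [SimConfig(n_bursts=n_bursts, seed=seed + 17 * i,
                      kinetics=KineticModel.static(efficiency=e))
            for i, e in enumerate(e_true)]


@dataclass
class CorrectionRecovery:
    recovered: CorrectionSet
    truth: CorrectionSet
    e_true: tuple
    e_recovered: list
    s_recovered: list


def run_correction_recovery(seed: int, n_bursts: int = 10000,
                            e_true=(0.3, 0.7)) -> CorrectionRecovery:
    """Full pipeline on the calibration pair; recovers all four factors and
    the accurate efficiencies."""
    subsets = []
    for cfg in calibration_pair_configs(seed, n_bursts, e_true):
        stream, _ = simulate_bursts(cfg)
        stream = assign_excitation(stream, cfg.scheme())
        bg = estimate_background(stream)
        subsets.append(select_bursts(search_bursts(stream, bg)))
    fret0 = subsets[0][0]
    donly = pd.concat([s[1] for s in subsets])
    aonly = pd.concat([s[2] for s in subsets])
    extra = [s[0] for s in subsets[1:]]
    recovered = derive_corrections(fret0, donly, aonly, extra_populations=extra)
    truth = implied_corrections(calibration_pair_configs(seed, 10, e_true)[0])
    es, ss = [], []
    for s in subsets:
        e, sv = population_center_ES(s[0], recovered)
        es.append(e)
        ss.append(sv)
    return CorrectionRecovery(recovered=recovered, truth=truth, e_true=tuple(e_true),
                              e_recovered=es, s_recovered=ss)


# ---------------------------------------------------------------------------
# dynamic PDA benchmark: slow exchange, broad detached ensemble vs compact state
# ---------------------------------------------------------------------------

PDA_TRUE_RELAXATION_MS = 10.0


def pda_slow_exchange_config(seed: int, n_bursts: int = 20000) -> SimConfig:
    """Two-state exchange between a broad detached ensemble (R = 60 A,
    sigma = 8 A) and a compact state (R = 45 A, sigma = 6 A linker width);
    relaxation time 10 ms with 25% compact occupancy."""
    kin = KineticModel.two_state(
        FretState(label="detached", distance=60.0, sigma_static=8.0),
        FretState(label="compact", distance=45.0, sigma_static=6.0),
        k12=25.0, k21=75.0)
    return SimConfig(n_bursts=n_bursts, seed=seed, kinetics=kin, dyes=IDEAL_DYES,
                     fractions=(1.0, 0.0, 0.0), bg_donor_hz=800.0, bg_acceptor_hz=600.0,
                     mean_gap_ms=400.0)  # very dilute: burst coincidence negligible


def run_pda_relaxation(seed: int, n_bursts: int = 20000,
                       windows_ms=(0.5, 1.0, 1.5, 2.0)):
    """Simulate, search bursts, chop windows, and fit the global dynamic PDA.

    Returns the :class:`~fretkit.dynamics.pda.PDAFitResult`; the benchmark
    quantity is ``relaxation_time_s``.
    """
    from .dynamics.pda import PDAModel, PDAStateSpec, fit_dynamic_pda, windows_from_bursts

    cfg = pda_slow_exchange_config(seed, n_bursts)
    stream, _ = simulate_bursts(cfg)
    stream = assign_excitation(stream, cfg.scheme())
    bg = estimate_background(stream)
    bursts = search_bursts(stream, bg)
    datasets = []
    for wms in windows_ms:
        w = windows_from_bursts(stream, bursts, wms)
        datasets.append({"window_s": wms * 1e-3, "windows": w,
                         "bg_d_mean": bg.rates_hz["DemDex"] * wms * 1e-3,
                         "bg_a_mean": bg.rates_hz["AemDex"] * wms * 1e-3})
    init = PDAModel(state1=PDAStateSpec(distance=58.0, sigma=9.0),
                    state2=PDAStateSpec(distance=47.0, sigma=6.0),
                    k12=50.0, k21=150.0, r0=cfg.forster_radius)
    return fit_dynamic_pda(datasets, init)


# ---------------------------------------------------------------------------
# filtered-FCS benchmark: two-timescale exchange
# ---------------------------------------------------------------------------

FCS_TRUE_TIMES_US = (9.0, 300.0)


def fcs_two_timescale_config(seed: int, n_bursts: int = 4000) -> SimConfig:
    """Three-state chain with eigen-relaxation times of exactly 9 us and
    300 us (fast within-ensemble exchange plus slower interconversion with a
    compact state); long transits (5 +/- 2 ms) in a large observation
    volume and nanosecond alternation so the excitation scheme does not
    imprint on microsecond correlations."""
    kin = three_state_chain(9e-6, 300e-6)
    return SimConfig(n_bursts=n_bursts, seed=seed, kinetics=kin, dyes=IDEAL_DYES,
                     fractions=(1.0, 0.0, 0.0),
                     duration_mean_ms=5.0, duration_sd_ms=2.0, mean_gap_ms=25.0,
                     bg_donor_hz=400.0, bg_acceptor_hz=300.0,
                     alternation_period_us=0.05, dex_window_us=(0.0, 0.025),
                     aex_window_us=(0.025, 0.05))


def run_fcs_relaxation(seed: int, n_bursts: int = 4000,
                       edge_quantiles=(0.15, 0.85)):
    """Filtered-FCS pipeline: edge-selected reference patterns, statistical
    filters, SACF/SCCF computation and the envelope-normalized global fit.

    Returns the :class:`~fretkit.dynamics.fcs.FCSResult` with the two
    recovered relaxation times (seconds, sorted ascending).
    """
    from .dynamics.fcs import (correlate, fit_species_curves, photon_weights,
                               reference_patterns, species_filters)

    cfg = fcs_two_timescale_config(seed, n_bursts)
    stream, _ = simulate_bursts(cfg)
    stream = assign_excitation(stream, cfg.scheme())
    bg = estimate_background(stream)
    fret, _, _ = select_bursts(search_bursts(stream, bg))
    q = np.quantile(fret["e_app"], list(edge_quantiles))
    patterns, total, photon_bin = reference_patterns(stream, fret, (0.0, q[0]), (q[1], 1.0))
    filters = species_filters(patterns, total)
    dexmask = stream.excitation == DEX
    w1, w2 = photon_weights(filters, photon_bin, dexmask)
    t = stream.times_s[dexmask]
    bg_frac = ((bg.rates_hz["DemDex"] + bg.rates_hz["AemDex"])
               * stream.duration_s / t.size)
    g_total = correlate(t, np.ones(t.size))
    curves = [correlate(t, w1[dexmask]), correlate(t, w2[dexmask]),
              correlate(t, w1[dexmask], w2[dexmask])]
    return fit_species_curves(curves, g_total, n_relaxations=2,
                              t_init_s=(1e-5, 3e-4), kappa=(1.0 - bg_frac) ** 2,
                              max_lag_s=2e-3)
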