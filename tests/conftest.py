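"""Shared fixtures: expensive simulated measurements are session-scoped."""

import numpy as np
import pytest

from fretkit.photon_data import assign_excitation
from fretkit.simulate import DyePhysics, KineticModel, FretState, SimConfig, simulate_bursts
from fretkit.bursts import estimate_background, search_bursts, select_bursts

IDEAL = DyePhysics(phi_d=1.0, phi_a=1.0, g_d=1.0, g_a=1.0, crosstalk=0.0,
                   direct_excitation=0.0, tau_d0_ns=4.0)


def analyzed(cfg):
    """Simulate, label, estimate background and search bursts."""
    stream, truth = simulate_bursts(cfg)
    stream = assign_excitation(stream, cfg.scheme())
    bg = estimate_background(stream)
    bursts = search_bursts(stream, bg)
    return stream, truth, bg, bursts


@pytest.fixture(scope="session")
def static_mixture_run():
    """Static E=0.5 measurement with consensus dye physics and a
    70/20/10 double/donor-only/acceptor-only species mixture."""
    cfg = SimConfig(n_bursts=6000, seed=301, kinetics=KineticModel.static(efficiency=0.5))
    stream, truth, bg, bursts = analyzed(cfg)
    fret, donly, aonly = select_bursts(bursts)
    return {"cfg": cfg, "stream": stream, "truth": truth, "bg": bg,
            "bursts": bursts, "fret": fret, "donor_only": donly, "acceptor_only": aonly}


@pytest.fixture(scope="session")
def static_linker_run():
    """Static molecule at R = R0 with fast 6 A linker fluctuations and
    ideal dye physics — the E-tau and BVA null dataset."""
    cfg = SimConfig(n_bursts=5000, seed=302, dyes=IDEAL, fractions=(1.0, 0.0, 0.0),
                    kinetics=KineticModel.static(distance=65.0, sigma_linker=6.0))
    stream, truth, bg, bursts = analyzed(cfg)
    fret, _, _ = select_bursts(bursts)
    return {"cfg": cfg, "stream": stream, "truth": truth, "bg": bg,
            "bursts": bursts, "fret": fret}


@pytest.fixture(scope="session")
def two_state_run():
    """Two-state exchange E = 0.2 <-> 0.8 with 0.5 ms relaxation — the
    dynamics positive control."""
    kin = KineticModel.two_state(FretState(efficiency=0.2), FretState(efficiency=0.8),
                                 k12=1000.0, k21=1000.0)
    cfg = SimConfig(n_bursts=5000, seed=303, dyes=IDEAL, fractions=(1.0, 0.0, 0.0),
                    kinetics=kin)
    stream, truth, bg, bursts = analyzed(cfg)
    fret, _, _ = select_bursts(bursts)
    return {"cfg": cfg, "stream": stream, "truth": truth, "bg": bg,
            "bursts": bursts, "fret": fret}
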