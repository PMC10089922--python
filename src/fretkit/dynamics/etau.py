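"""FRET efficiency versus fluorescence-weighted donor lifetime analysis.

For a static molecule the intensity-derived efficiency E and the donor
lifetime tau_D(A) obey E = 1 - tau/tau_D(0); flexible-linker distance
fluctuations (sigma ~ 6 A) bend this *static FRET line* slightly upward.
A population undergoing slower-than-lifetime exchange between two states
falls on the *dynamic FRET line* connecting the states, to the right of the
static line, because the single fitted lifetime is photon-weighted toward
the low-FRET state.  The vertical offset of a population center from the
static line is the E-tau dynamic shift ds; inverting a symmetric two-state
model (distances R +/- dR, equal occupancy) converts ds into a distance
fluctuation amplitude dR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from ..photon_data import DEX, PhotonStream
from ..simulate import forster_efficiency
from .bva import clipped_center_2d

__all__ = [
    "burst_lifetime",
    "burst_lifetimes",
    "StaticLine",
    "static_fret_line",
    "dynamic_fret_line",
    "dynamic_shift_etau",
    "estimate_delta_R",
    "two_state_observables",
]


def burst_lifetime(
    microtimes_ns: np.ndarray,
    t_start_ns: float,
    t_stop_ns: float,
    bg_fraction: float = 0.0,
    tau_bounds_ns: tuple[float, float] = (0.05, 10.0),
    min_photons: int = 20,
) -> float:
    """ML single-exponential lifetime with a flat background term.

    The IRF is handled by a tail start: only photons with microtime in
    ``[t_start_ns, t_stop_ns)`` enter, and the decay is referenced to
    ``t_start_ns``.  The likelihood per photon is
    ``(1-f) Exp(tau; truncated to the window) + f Uniform(window)`` with
    ``f`` the expected background fraction.  Returns NaN for bursts with
    fewer than ``min_photons`` usable photons.
    """
    t = np.asarray(microtimes_ns, dtype=float)
    t = t[(t >= t_start_ns) & (t < t_stop_ns)] - t_start_ns
    if t.size < min_photons:
        return np.nan
    window = t_stop_ns - t_start_ns
    f = min(max(bg_fraction, 0.0), 0.95)

    def nll(tau):
        z = tau * (1.0 - np.exp(-window / tau))
        p = (1.0 - f) * np.exp(-t / tau) / z + f / window
        return -np.sum(np.log(np.maximum(p, 1e-300)))

    res = minimize_scalar(nll, bounds=tau_bounds_ns, method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


def burst_lifetimes(
    stream: PhotonStream,
    bursts: pd.DataFrame,
    tau_d0_ns: float,
    bg_rate_hz: float = 0.0,
    t_start_ns: Optional[float] = None,
    min_photons: int = 20,
) -> np.ndarray:
    """Fluorescence-weighted donor lifetime per burst (NaN when too dim).

    Uses donor-channel Dex photons.  ``bg_rate_hz`` is the DemDex background
    rate; the per-burst background fraction is rate x duration / counts.
    ``t_start_ns`` defaults to the IRF position stored by the simulator
    (meta) plus 3 IRF widths, else 2.5 ns.
    """
    if stream.microtimes is None:
        raise ValueError("burst lifetimes require microtimes")
    res_ns = stream.microtime_resolution_ps * 1e-3
    t_stop_ns = stream.microtime_range * res_ns
    if t_start_ns is None:
        t_start_ns = 2.75
    t = stream.times_s
    band = stream.band()
    mask = (band == 0) & (stream.excitation == DEX)
    t_d = t[mask]
    mt_d = stream.microtimes[mask] * res_ns

    out = np.full(len(bursts), np.nan)
    for i, (t0, t1, dur_ms) in enumerate(zip(bursts["start_s"], bursts["stop_s"],
                                             bursts["duration_ms"])):
        i0 = np.searchsorted(t_d, t0)
        i1 = np.searchsorted(t_d, t1, side="right")
        nph = i1 - i0
        if nph < min_photons:
            continue
        bg_frac = min(bg_rate_hz * dur_ms * 1e-3 / nph, 0.9)
        out[i] = burst_lifetime(mt_d[i0:i1], t_start_ns, t_stop_ns, bg_frac,
                                tau_bounds_ns=(0.05, 1.2 * tau_d0_ns),
                                min_photons=min_photons)
    return out


@dataclass
class StaticLine:
    """Sampled static FRET line E(<tau>_F) plus a cubic approximation.

    ``tau`` and ``e`` sample the curve densely (quadrature truth); ``poly``
    is a least-squares cubic in tau for fast evaluation.  Calling the object
    interpolates the sampled curve.
    """

    tau: np.ndarray
    e: np.ndarray
    poly: np.ndarray
    tau_d0_ns: float
    sigma_linker: float

    def __call__(self, tau_ns):
        tau_ns = np.asarray(tau_ns, dtype=float)
        out = np.interp(tau_ns, self.tau, self.e)
        return out if out.ndim else float(out)


def static_fret_line(
    tau_d0_ns: float,
    sigma_linker: float = 6.0,
    r0: float = 65.0,
    n_quad: int = 129,
    n_points: int = 200,
) -> StaticLine:
    """Static FRET line, linker-corrected by Gaussian distance averaging.

    For each central distance Rc the interdye distance is N(Rc, sigma);
    the intensity efficiency is the species average <E> and the lifetime
    axis carries the photon-weighted <tau>_F = <tau^2>/<tau> with
    tau(R) = tau_D(0) (1 - E(R)).  sigma_linker = 0 reduces exactly to
    E = 1 - tau/tau_D(0).
    """
    if tau_d0_ns <= 0:
        raise ValueError("tau_D(0) must be positive")
    if sigma_linker == 0:
        tau = np.linspace(0.0, tau_d0_ns, n_points)
        e = 1.0 - tau / tau_d0_ns
        poly = np.polyfit(tau, e, 3)
        return StaticLine(tau=tau, e=e, poly=poly, tau_d0_ns=tau_d0_ns, sigma_linker=0.0)

    # Gauss-Legendre over +/- 6 sigma around each central distance
    from numpy.polynomial.legendre import leggauss

    x, wq = leggauss(n_quad)
    rc = np.geomspace(0.25 * r0, 3.5 * r0, n_points)
    tau_curve = np.empty(n_points)
    e_curve = np.empty(n_points)
    for i, c in enumerate(rc):
        r = c + 6.0 * sigma_linker * x
        w = wq * np.exp(-((r - c) ** 2) / (2 * sigma_linker**2))
        ok = r > 1e-6
        r, w = r[ok], w[ok]
        w = w / w.sum()
        e_r = forster_efficiency(r, r0)
        tau_r = tau_d0_ns * (1.0 - e_r)
        e_curve[i] = float(np.sum(w * e_r))
        tau_curve[i] = float(np.sum(w * tau_r**2) / np.sum(w * tau_r))
    order = np.argsort(tau_curve)
    tau_curve, e_curve = tau_curve[order], e_curve[order]
    poly = np.polyfit(tau_curve, e_curve, 3)
    return StaticLine(tau=tau_curve, e=e_curve, poly=poly,
                      tau_d0_ns=tau_d0_ns, sigma_linker=sigma_linker)


def dynamic_fret_line(e1: float, e2: float, tau_d0_ns: float, n_points: int = 100):
    """Two-state mixing curve connecting states (E1, tau1) and (E2, tau2).

    tau_i = tau_D(0) (1 - E_i); along the curve
    E(<tau>_F) = 1 - [tau1 tau2 / (tau1 + tau2 - <tau>_F)] / tau_D(0).
    Returns (tau array, E array, callable).  The callable raises outside
    [min(tau1, tau2), max(tau1, tau2)].
    """
    tau1 = tau_d0_ns * (1.0 - e1)
    tau2 = tau_d0_ns * (1.0 - e2)
    lo, hi = min(tau1, tau2), max(tau1, tau2)

    def curve(tau_f):
        tau_f = np.asarray(tau_f, dtype=float)
        if np.any(tau_f < lo - 1e-9) or np.any(tau_f > hi + 1e-9):
            raise ValueError(f"<tau>_F outside the state interval [{lo:.3g}, {hi:.3g}] ns")
        out = 1.0 - (tau1 * tau2 / (tau1 + tau2 - tau_f)) / tau_d0_ns
        return out if out.ndim else float(out)

    tau = np.linspace(lo, hi, n_points)
    return tau, curve(tau) if lo < hi else np.full(n_points, e1), curve


def dynamic_shift_etau(center_tau_ns: float, center_e: float, static_line) -> float:
    """ds = E_0 - E_static(tau_0): signed vertical offset of the population
    center from the static FRET line."""
    if isinstance(static_line, StaticLine):
        if not (static_line.tau.min() - 1e-9 <= center_tau_ns <= static_line.tau.max() + 1e-9):
            raise ValueError("population lifetime outside the static-line domain")
    return float(center_e - static_line(center_tau_ns))


def two_state_observables(r_center: float, delta_r: float, r0: float,
                          tau_d0_ns: float) -> tuple[float, float]:
    """(<tau>_F, E) of equal-occupancy exchange between distances R +/- dR.

    Intensity E is the occupancy average of the state efficiencies; the
    lifetime is donor-photon weighted: <tau>_F = sum p(1-E)tau / sum p(1-E).
    """
    r1, r2 = max(r_center - delta_r, 1e-3), r_center + delta_r
    e1, e2 = forster_efficiency(r1, r0), forster_efficiency(r2, r0)
    e_obs = 0.5 * (e1 + e2)
    w1, w2 = 1.0 - e1, 1.0 - e2
    tau1, tau2 = tau_d0_ns * w1, tau_d0_ns * w2
    tau_f = (w1 * tau1 + w2 * tau2) / (w1 + w2)
    return float(tau_f), float(e_obs)


@dataclass
class FluctuationEstimate:
    delta_r: float
    ds_input: float
    r_center: float
    converged: bool


def estimate_delta_R(
    ds: float,
    r_center: float,
    r0: float,
    tau_d0_ns: float,
    static_line=None,
    max_delta_r: Optional[float] = None,
) -> FluctuationEstimate:
    """Distance-fluctuation amplitude dR reproducing an observed dynamic shift.

    Assumes equal-occupancy two-state dynamics between R<E> +/- dR and
    numerically inverts the forward model (dynamic shift of the mixed
    population from the static line).  ds <= 0 returns dR = 0.
    """
    if static_line is None:
        line = lambda tau: 1.0 - np.asarray(tau) / tau_d0_ns  # noqa: E731
    else:
        line = static_line
    if ds <= 0:
        return FluctuationEstimate(delta_r=0.0, ds_input=ds, r_center=r_center, converged=True)
    hi = max_delta_r if max_delta_r is not None else 0.9 * r_center

    def model_ds(dr):
        tau_f, e_obs = two_state_observables(r_center, dr, r0, tau_d0_ns)
        return e_obs - float(line(tau_f))

    f_hi = model_ds(hi)
    if f_hi < ds:
        raise RuntimeError(
            f"dR inversion bracket failed: ds={ds:.4g} above model maximum "
            f"{f_hi:.4g} at dR={hi:.3g} A")
    dr = brentq(lambda x: model_ds(x) - ds, 0.0, hi, xtol=1e-6)
    return FluctuationEstimate(delta_r=float(dr), ds_input=ds, r_center=r_center,
                               converged=True)


def etau_population_center(e: np.ndarray, tau_ns: np.ndarray) -> tuple[float, float]:
    """Sigma-clipped 2D Gaussian center of the (tau, E) scatter -> (tau0, E0)."""
    t0, e0 = clipped_center_2d(tau_ns, e)
    return t0, e0
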