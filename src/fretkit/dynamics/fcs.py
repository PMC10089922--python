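"""FRET- and filtered fluorescence correlation spectroscopy.

Filtered FCS separates spectroscopic species by their fluorescence decay
patterns: reference patterns over (detection channel x TCSPC microtime bin)
are built from subensembles selected at the edges of the FRET efficiency
histogram, statistical filters are solved from the unbiasedness condition
(each filter, applied to the total pattern, returns one species' photons on
average), and species auto-/cross-correlation functions (SACF/SCCF) are
computed by weighted photon-pair correlation on a quasi-logarithmic lag
grid.  Kinetic exchange between the species appears as relaxation terms:
SACFs decay with extra positive amplitude, SCCFs show anticorrelation, and
a global fit of diffusion x (1 + sum_i A_i exp(-tau/t_R,i)) recovers the
relaxation times shared by all curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from ..photon_data import DEX, PhotonStream

__all__ = [
    "species_filters",
    "reference_patterns",
    "photon_weights",
    "correlate",
    "CorrelationCurve",
    "FCSResult",
    "fit_fcs",
    "kinetic_ratio",
    "fit_kinetic_ratios",
    "fit_species_curves",
]


def species_filters(patterns: np.ndarray, total_pattern: np.ndarray) -> np.ndarray:
    """Statistical filter weights per species and histogram bin.

    ``patterns``: (n_species, n_bins) normalized reference patterns;
    ``total_pattern``: expected counts per bin of the full measurement
    (the variance proxy of the weighted least-squares solution).  Solves
    ``F = (M D M^T)^-1 M D`` with ``D = diag(1/total)``; bins with zero
    total are excluded.  The filters satisfy sum_s w_s,b a_s = 1 per bin
    for the amplitudes implied by the total pattern (unbiasedness).
    """
    m = np.asarray(patterns, dtype=float)
    if m.ndim != 2:
        raise ValueError("patterns must be (n_species, n_bins)")
    tot = np.asarray(total_pattern, dtype=float)
    ok = tot > 0
    m_ok = m[:, ok]
    rank = np.linalg.matrix_rank(m_ok, tol=1e-10 * np.abs(m_ok).max())
    if rank < m.shape[0]:
        raise np.linalg.LinAlgError("reference patterns are collinear; species "
                                    "cannot be separated")
    d = 1.0 / tot[ok]
    gram = (m_ok * d) @ m_ok.T
    try:
        filt_ok = np.linalg.solve(gram, m_ok * d)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("filter conditioning failed: " + str(err)) from err
    filters = np.zeros_like(m)
    filters[:, ok] = filt_ok
    return filters


def reference_patterns(
    stream: PhotonStream,
    bursts: pd.DataFrame,
    e_low: tuple[float, float],
    e_high: tuple[float, float],
    n_micro_bins: int = 64,
    e_column: str = "e_app",
):
    """Species patterns from E-range-selected subensembles of the measurement.

    Two reference species are defined at the lower and upper edge of the
    FRET efficiency histogram (``e_low``/``e_high`` are (min, max) ranges on
    ``e_column``).  Returns ``(patterns (2, 2*n_micro_bins), total_pattern,
    bin_of_photon function)`` where patterns run over donor-channel
    microtime bins followed by acceptor-channel bins (Dex photons only).
    """
    if stream.microtimes is None:
        raise ValueError("filtered FCS requires microtimes")
    t = stream.times_s
    band = stream.band()
    dexmask = stream.excitation == DEX
    nbins_total = 2 * n_micro_bins
    micro_edges = np.linspace(0, stream.microtime_range, n_micro_bins + 1)
    mbin = np.clip(np.digitize(stream.microtimes, micro_edges) - 1, 0, n_micro_bins - 1)
    photon_bin = np.where(band == 0, mbin, n_micro_bins + mbin)

    def pattern_for(sel_bursts):
        acc = np.zeros(nbins_total)
        for t0, t1 in zip(sel_bursts["start_s"], sel_bursts["stop_s"]):
            i0, i1 = np.searchsorted(t, [t0, t1 + 1e-12])
            sl = slice(i0, i1)
            bins = photon_bin[sl][dexmask[sl]]
            acc += np.bincount(bins, minlength=nbins_total)
        s = acc.sum()
        return acc / s if s > 0 else acc

    e = bursts[e_column].to_numpy(float)
    low = bursts[(e >= e_low[0]) & (e <= e_low[1])]
    high = bursts[(e >= e_high[0]) & (e <= e_high[1])]
    if len(low) < 10 or len(high) < 10:
        raise ValueError("too few bursts in a reference E range")
    patterns = np.vstack([pattern_for(low), pattern_for(high)])
    total = np.zeros(nbins_total)
    bins_all = photon_bin[dexmask]
    total += np.bincount(bins_all, minlength=nbins_total)
    return patterns, total, photon_bin


def photon_weights(filters: np.ndarray, photon_bin: np.ndarray,
                   mask: np.ndarray) -> list[np.ndarray]:
    """Per-photon filter weights for each species (photons outside ``mask``
    get weight 0)."""
    out = []
    for f in filters:
        w = np.zeros(photon_bin.size)
        w[mask] = f[photon_bin[mask]]
        out.append(w)
    return out


@njit(cache=True)
def _pair_correlate(t, w1, w2, edges):
    nb = edges.size - 1
    num = np.zeros(nb)
    npairs = np.zeros(nb)
    n = t.size
    tmax = edges[-1]
    for i in range(n):
        k = 0
        ti = t[i]
        for j in range(i + 1, n):
            dt = t[j] - ti
            if dt >= tmax:
                break
            if dt < edges[0]:
                continue
            while dt >= edges[k + 1]:
                k += 1
            num[k] += w1[i] * w2[j] + w2[i] * w1[j]
            npairs[k] += 1.0
    return num, npairs


@dataclass
class CorrelationCurve:
    """Normalized correlation G(tau) on a quasi-logarithmic lag grid."""

    lag_s: np.ndarray
    g: np.ndarray
    sigma: np.ndarray
    label: str = ""


def correlate(
    times_s: np.ndarray,
    weights_1: np.ndarray,
    weights_2: Optional[np.ndarray] = None,
    lag_min_s: float = 1e-6,
    lag_max_s: float = 0.1,
    n_lags: int = 48,
) -> CorrelationCurve:
    """Photon-pair correlation of (weighted) photon streams.

    G(tau) = <w1(t) w2(t+tau)> / (<w1><w2>) - 1, computed directly from
    photon pairs on logarithmically spaced lag bins and normalized so that
    an uncorrelated (Poisson) stream gives G = 0.
    """
    t = np.asarray(times_s, dtype=np.float64)
    if t.size == 0:
        raise ValueError("empty photon stream")
    w1 = np.asarray(weights_1, dtype=np.float64)
    w2 = w1 if weights_2 is None else np.asarray(weights_2, dtype=np.float64)
    edges = np.geomspace(lag_min_s, lag_max_s, n_lags + 1)
    num, npairs = _pair_correlate(t, w1, w2, edges)
    span = t[-1] - t[0]
    widths = np.diff(edges)
    mid = np.sqrt(edges[:-1] * edges[1:])
    s1, s2 = w1.sum(), w2.sum()
    # finite-trace correction: pairs at lag tau can only start in (span - tau)
    expected = 2.0 * s1 * s2 * widths * (span - mid) / span**2
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, num / expected - 1.0, np.nan)
        sigma = np.where(npairs > 0, (1.0 + np.abs(g)) / np.sqrt(npairs), np.inf)
    return CorrelationCurve(lag_s=mid, g=g, sigma=sigma)


@dataclass
class FCSResult:
    relaxation_times_s: np.ndarray
    amplitudes: dict
    diffusion_time_s: float
    chi2_red: float
    params: object
    boundary_warning: bool


def fit_fcs(
    curves: Sequence[CorrelationCurve],
    n_relaxations: int = 2,
    t_init_s: Sequence[float] = (1e-5, 3e-4),
    diffusion_init_s: float = 2e-3,
    fit_range_s: tuple[float, float] = (0.0, 5e-3),
    sigma_floor_rel: float = 0.02,
) -> FCSResult:
    """Global fit of SACF/SCCF curves with shared kinetic relaxation times.

    Model per curve: G = G0 / (1 + tau/tau_d) x (1 + sum_i A_i exp(-tau/t_i));
    amplitudes are free per curve (negative allowed — SCCF anticorrelation),
    the diffusion time tau_d and the relaxation times t_i are shared.  The
    fit range excludes long lags where the single-component transit term
    cannot follow the burst-gap structure; ``sigma_floor_rel`` adds a
    relative error floor so densely sampled lags do not dominate.
    """
    import lmfit

    if len(curves) < 2:
        raise ValueError("global FCS fit needs >= 2 curves")
    p = lmfit.Parameters()
    p.add("log_tau_d", value=np.log10(diffusion_init_s), min=-5, max=0)
    for i in range(n_relaxations):
        p.add(f"log_t{i}", value=np.log10(t_init_s[i]), min=-6.5, max=-1)
    g0_init = [max(np.nanmedian(c.g[np.isfinite(c.g)][-8:]), 0.1) for c in curves]
    for c_ix, c in enumerate(curves):
        p.add(f"g0_{c_ix}", value=g0_init[c_ix])
        for i in range(n_relaxations):
            p.add(f"a{i}_{c_ix}", value=0.3 if i == 0 else 0.1, min=-30, max=300)

    def model_curve(params, c_ix, lag):
        tau_d = 10.0 ** params["log_tau_d"].value
        g = np.ones_like(lag)
        for i in range(n_relaxations):
            ti = 10.0 ** params[f"log_t{i}"].value
            g = g + params[f"a{i}_{c_ix}"].value * np.exp(-lag / ti)
        return params[f"g0_{c_ix}"].value / (1.0 + lag / tau_d) * g

    masks = []
    for c in curves:
        ok = (np.isfinite(c.g) & (c.lag_s >= fit_range_s[0])
              & (c.lag_s <= fit_range_s[1]) & np.isfinite(c.sigma))
        masks.append(ok)

    def residuals(params):
        res = []
        for c_ix, c in enumerate(curves):
            ok = masks[c_ix]
            sig = np.hypot(c.sigma[ok], sigma_floor_rel * (1.0 + np.abs(c.g[ok])))
            res.append((c.g[ok] - model_curve(params, c_ix, c.lag_s[ok])) / sig)
        return np.concatenate(res)

    out = lmfit.minimize(residuals, p, method="leastsq", max_nfev=3000)
    times = np.sort([10.0 ** out.params[f"log_t{i}"].value for i in range(n_relaxations)])
    lag_lo = min(c.lag_s[masks[i]].min() for i, c in enumerate(curves))
    lag_hi = max(c.lag_s[masks[i]].max() for i, c in enumerate(curves))
    boundary = bool(times[0] <= lag_lo * 1.5 or times[-1] >= lag_hi / 1.5)
    amps = {f"curve{c_ix}": [out.params[f"a{i}_{c_ix}"].value for i in range(n_relaxations)]
            for c_ix in range(len(curves))}
    return FCSResult(relaxation_times_s=times, amplitudes=amps,
                     diffusion_time_s=10.0 ** out.params["log_tau_d"].value,
                     chi2_red=float(out.redchi), params=out.params,
                     boundary_warning=boundary)


def kinetic_ratio(curve: CorrelationCurve, total: CorrelationCurve,
                  min_total_frac: float = 0.1,
                  max_lag_s: float = 3e-3) -> CorrelationCurve:
    """Divide a species correlation by the total (unfiltered) correlation.

    When the total detected brightness is independent of the FRET state, the
    total autocorrelation carries only the transit/occupation envelope, so
    the ratio G_s / G_tot isolates the kinetic factor
    b (1 + sum_i A_i exp(-tau/t_R,i)) without any transit model.  Lags past
    ``max_lag_s`` or where the total correlation has decayed below
    ``min_total_frac`` of its peak are masked (the ratio degenerates there).
    """
    if curve.lag_s.shape != total.lag_s.shape or not np.allclose(curve.lag_s, total.lag_s):
        raise ValueError("curves must share the lag grid")
    gmax = np.nanmax(total.g)
    ok = (np.isfinite(total.g) & (total.g > min_total_frac * gmax)
          & np.isfinite(curve.g) & (curve.lag_s <= max_lag_s))
    g = np.where(ok, curve.g / np.where(ok, total.g, 1.0), np.nan)
    sigma = np.where(ok, np.hypot(curve.sigma / np.where(ok, total.g, 1.0),
                                  g * total.sigma / np.where(ok, total.g, 1.0)), np.inf)
    return CorrelationCurve(lag_s=curve.lag_s, g=g, sigma=sigma,
                            label=f"{curve.label}/total")


def fit_kinetic_ratios(
    ratio_curves: Sequence[CorrelationCurve],
    n_relaxations: int = 2,
    t_init_s: Sequence[float] = (1e-5, 3e-4),
    sigma_floor_rel: float = 0.01,
) -> FCSResult:
    """Global fit of transit-normalized curves: b_c (1 + sum A_ci e^(-tau/t_i)).

    Relaxation times are shared across curves; baselines and amplitudes are
    free per curve (negative amplitudes capture SCCF anticorrelation).
    """
    import lmfit

    p = lmfit.Parameters()
    for i in range(n_relaxations):
        p.add(f"log_t{i}", value=np.log10(t_init_s[i]), min=-6.5, max=-1)
    for c_ix, c in enumerate(ratio_curves):
        ok = np.isfinite(c.g)
        base = float(np.nanmedian(c.g[ok][-6:])) if ok.sum() >= 6 else 1.0
        p.add(f"b_{c_ix}", value=base)
        for i in range(n_relaxations):
            p.add(f"a{i}_{c_ix}", value=0.2 if i == 0 else 0.1, min=-50, max=300)

    def model_curve(params, c_ix, lag):
        g = np.ones_like(lag)
        for i in range(n_relaxations):
            ti = 10.0 ** params[f"log_t{i}"].value
            g = g + params[f"a{i}_{c_ix}"].value * np.exp(-lag / ti)
        return params[f"b_{c_ix}"].value * g

    masks = [np.isfinite(c.g) & np.isfinite(c.sigma) for c in ratio_curves]

    def residuals(params):
        res = []
        for c_ix, c in enumerate(ratio_curves):
            ok = masks[c_ix]
            sig = np.hypot(c.sigma[ok], sigma_floor_rel * (1.0 + np.abs(c.g[ok])))
            res.append((c.g[ok] - model_curve(params, c_ix, c.lag_s[ok])) / sig)
        return np.concatenate(res)

    out = lmfit.minimize(residuals, p, method="leastsq", max_nfev=3000)
    times = np.sort([10.0 ** out.params[f"log_t{i}"].value for i in range(n_relaxations)])
    finite = [c.lag_s[masks[i]] for i, c in enumerate(ratio_curves) if masks[i].any()]
    lag_lo = min(l.min() for l in finite)
    lag_hi = max(l.max() for l in finite)
    boundary = bool(times[0] <= lag_lo * 1.5 or times[-1] >= lag_hi / 1.5)
    amps = {f"curve{c_ix}": [out.params[f"a{i}_{c_ix}"].value for i in range(n_relaxations)]
            for c_ix in range(len(ratio_curves))}
    return FCSResult(relaxation_times_s=times, amplitudes=amps,
                     diffusion_time_s=np.nan, chi2_red=float(out.redchi),
                     params=out.params, boundary_warning=boundary)


def fit_species_curves(
    curves: Sequence[CorrelationCurve],
    total: CorrelationCurve,
    n_relaxations: int = 2,
    t_init_s: Sequence[float] = (1e-5, 3e-4),
    max_lag_s: float = 5e-3,
    min_total_frac: float = 0.02,
    sigma_floor_rel: float = 0.02,
    kappa: Optional[float] = None,
) -> FCSResult:
    """Global kinetic fit using the measured total correlation as envelope.

    For molecules whose total detected brightness is state-independent, each
    species curve factorizes as

        G_s(tau) = a_c G_P(tau) + a_c g_k(tau) (1 + G_P(tau)),

    with G_P the molecule-occupation (transit) correlation and
    g_k = sum_i A_i exp(-tau/t_R,i) the kinetic factor.  The total
    autocorrelation supplies the envelope shape data-driven,
    E(tau) = kappa G_P(tau), where kappa = (signal / (signal+background))^2
    is the background dilution of the total curve — pass the measured value
    via ``kappa`` (it is in (0, 1]; left free it is fitted inside those
    bounds).  Fitted model per curve:
    G = a_c E + (sum_i A_ci e^(-tau/t_i)) (1 + E/kappa); relaxation times
    and kappa shared across curves.
    """
    import lmfit

    env = np.where(np.isfinite(total.g), total.g, 0.0)
    gmax = np.nanmax(env)
    base_ok = (np.isfinite(total.g) & (env > min_total_frac * gmax))

    p = lmfit.Parameters()
    for i in range(n_relaxations):
        p.add(f"log_t{i}", value=np.log10(t_init_s[i]), min=-6.5, max=-1)
    p.add("kappa", value=kappa if kappa is not None else 0.8,
          min=0.01, max=1.0, vary=kappa is None)
    for c_ix, c in enumerate(curves):
        ok = base_ok & np.isfinite(c.g)
        a0 = float(np.nanmedian(c.g[ok] / env[ok])) if ok.sum() else 1.0
        p.add(f"a_{c_ix}", value=a0)
        for i in range(n_relaxations):
            p.add(f"A{i}_{c_ix}", value=0.05 if i else 0.1, min=-10, max=10)

    masks = [base_ok & np.isfinite(c.g) & (c.lag_s <= max_lag_s) for c in curves]

    def model_curve(params, c_ix, ok):
        e = env[ok]
        gk = np.zeros(ok.sum())
        for i in range(n_relaxations):
            ti = 10.0 ** params[f"log_t{i}"].value
            gk = gk + params[f"A{i}_{c_ix}"].value * np.exp(-total.lag_s[ok] / ti)
        kap = params["kappa"].value
        return params[f"a_{c_ix}"].value * e + gk * (1.0 + e / kap)

    def residuals(params):
        res = []
        for c_ix, c in enumerate(curves):
            ok = masks[c_ix]
            sig = np.hypot(c.sigma[ok], sigma_floor_rel * (1.0 + np.abs(c.g[ok])))
            res.append((c.g[ok] - model_curve(params, c_ix, ok)) / sig)
        return np.concatenate(res)

    out = lmfit.minimize(residuals, p, method="leastsq", max_nfev=4000)
    times = np.sort([10.0 ** out.params[f"log_t{i}"].value for i in range(n_relaxations)])
    finite = [c.lag_s[masks[i]] for i, c in enumerate(curves) if masks[i].any()]
    lag_lo = min(l.min() for l in finite)
    lag_hi = max(l.max() for l in finite)
    boundary = bool(times[0] <= lag_lo * 1.5 or times[-1] >= lag_hi / 1.5)
    amps = {f"curve{c_ix}": [out.params[f"A{i}_{c_ix}"].value for i in range(n_relaxations)]
            for c_ix in range(len(curves))}
    return FCSResult(relaxation_times_s=times, amplitudes=amps,
                     diffusion_time_s=np.nan, chi2_red=float(out.redchi),
                     params=out.params, boundary_warning=boundary)
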