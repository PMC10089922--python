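"""Dynamic photon distribution analysis (PDA).

PDA models the shot-noise-limited histogram of apparent FRET efficiencies
computed over fixed time windows cut from bursts.  For a molecule
exchanging between two states, the fraction of window time spent in state 1
follows the two-state telegraph occupancy distribution (atoms at 0 and 1
for windows without transitions plus a continuous bridge); acceptor counts
are binomial given the occupancy-averaged efficiency; quasi-static Gaussian
distance broadening per state and Poisson background counts per channel are
convolved in.  Fitting histograms at several window lengths (0.5-2 ms)
globally constrains the exchange rates: the observable is the growth of the
transition-mixed fraction with window length, and the recovered relaxation
time is 1/(k12 + k21).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import poisson

from ..photon_data import DEX, PhotonStream
from ..simulate import forster_efficiency

__all__ = [
    "occupancy_distribution",
    "PDAStateSpec",
    "PDAModel",
    "windows_from_bursts",
    "pda_predict",
    "fit_dynamic_pda",
]


def occupancy_distribution(k1: float, k2: float, window_s: float, n_grid: int = 40,
                           tol: float = 1e-10):
    """Distribution of the state-1 occupancy fraction over a window.

    Two-state Markov exchange with rates ``k1`` (leave state 1) and ``k2``
    (leave state 2), stationary initial condition.  Returns
    ``(x, w, w_atom0, w_atom1)``: midpoint grid of interior occupancy
    fractions with weights, plus the no-transition atoms at x = 0 (all
    state 2) and x = 1 (all state 1).  Computed by the renewal series over
    the number of transitions, truncated when terms fall below ``tol``.
    """
    T = window_s
    ktot = k1 + k2
    p1 = k2 / ktot if ktot > 0 else 1.0
    p2 = 1.0 - p1
    w_atom1 = p1 * np.exp(-k1 * T)
    w_atom0 = p2 * np.exp(-k2 * T)
    x = (np.arange(n_grid) + 0.5) / n_grid
    t1 = x * T
    t2 = T - t1
    a = k1 * t1
    b = k2 * t2
    log_a = np.log(np.maximum(a, 1e-300))
    log_b = np.log(np.maximum(b, 1e-300))
    dens = np.zeros(n_grid)
    base = -a - b
    # the term magnitudes peak near n ~ kT (mean transition count): iterate
    # well past the peak before applying the smallness cutoff
    n_peak = max(k1 * T, k2 * T)
    n_max = int(max(200, 4 * n_peak))
    for n in range(1, n_max):
        # tXY: path starting in state X with the last (censored) dwell in Y;
        # n complete dwells in the recurring state, Gamma densities in t1/t2
        t11 = np.exp(base + n * log_a - gammaln(n + 1) + (n - 1) * log_b - gammaln(n)) * k2
        t12 = np.exp(base + (n - 1) * log_a - gammaln(n) + (n - 1) * log_b - gammaln(n)) * k1
        t22 = np.exp(base + n * log_b - gammaln(n + 1) + (n - 1) * log_a - gammaln(n)) * k1
        t21 = np.exp(base + (n - 1) * log_b - gammaln(n) + (n - 1) * log_a - gammaln(n)) * k2
        term = p1 * (t11 + t12) + p2 * (t22 + t21)
        dens += term
        if n > n_peak and np.max(term) * T / n_grid < tol:
            break
    w = dens * T / n_grid
    # midpoint-rule error lands in the interior weights only: the atoms are
    # exact closed forms, so renormalize the interior to the exact remainder
    interior = 1.0 - w_atom0 - w_atom1
    if w.sum() > 0:
        w = w * (interior / w.sum())
    return x, w, w_atom0, w_atom1


@dataclass(frozen=True)
class PDAStateSpec:
    """One PDA state: center distance (Angstrom) and quasi-static Gaussian
    broadening, or a fixed efficiency."""

    distance: Optional[float] = None
    sigma: float = 0.0
    efficiency: Optional[float] = None

    def e_nodes(self, r0: float, n_nodes: int = 16):
        """(efficiency nodes, weights) via Gauss-Hermite over the distance."""
        if self.efficiency is not None:
            return np.array([self.efficiency]), np.array([1.0])
        if self.sigma <= 0:
            return np.array([float(forster_efficiency(self.distance, r0))]), np.array([1.0])
        nodes, wts = np.polynomial.hermite_e.hermegauss(n_nodes)
        r = self.distance + self.sigma * nodes
        ok = r > 1.0
        w = wts[ok] / wts[ok].sum()
        return np.asarray(forster_efficiency(r[ok], r0)), w


@dataclass
class PDAModel:
    """Two dynamic states with exchange rates, plus optional static components.

    ``extra_static``: list of (state spec, fraction) mixed into the window
    ensemble as molecules that never exchange (e.g. a residual ligand-free
    population); fractions refer to the window population.
    """

    state1: PDAStateSpec
    state2: PDAStateSpec
    k12: float
    k21: float
    r0: float = 65.0
    extra_static: list = field(default_factory=list)

    @property
    def relaxation_time_s(self) -> float:
        return 1.0 / (self.k12 + self.k21)


def windows_from_bursts(stream: PhotonStream, bursts: pd.DataFrame,
                        window_ms: float, min_fill: float = 0.85) -> pd.DataFrame:
    """Chop bursts into consecutive complete windows of fixed length.

    Returns one row per window with total Dex photon count ``n`` and
    acceptor count ``k``.  Windows whose count falls below ``min_fill``
    times the burst's own mean rate x window length are dropped: such
    windows overlap the burst edges, where search padding mixes in
    background-only stretches.  Selection on the total count alone does not
    bias the PDA model (the count distribution enters empirically).
    """
    if stream.excitation is None:
        raise ValueError("assign_excitation must run first")
    t = stream.times_s
    band = stream.band()
    dex = stream.excitation == DEX
    t_dex = t[dex]
    a_dex = (band[dex] == 1).astype(np.int8)
    w = window_ms * 1e-3
    rows = []
    for t0, t1 in zip(bursts["start_s"], bursts["stop_s"]):
        n_win = int((t1 - t0) / w)
        if n_win == 0:
            continue
        j0 = np.searchsorted(t_dex, t0)
        j1 = np.searchsorted(t_dex, t1, side="right")
        burst_rate = (j1 - j0) / (t1 - t0)
        n_min = min_fill * burst_rate * w
        for j in range(n_win):
            i0 = np.searchsorted(t_dex, t0 + j * w)
            i1 = np.searchsorted(t_dex, t0 + (j + 1) * w)
            if i1 - i0 >= n_min and i1 > i0:
                rows.append((i1 - i0, int(a_dex[i0:i1].sum())))
    return pd.DataFrame(rows, columns=["n", "k"])


class _PredictCache:
    """Binomial pmf tables over a fixed efficiency grid, reused across fit
    iterations (they do not depend on the model parameters)."""

    def __init__(self, e_grid: np.ndarray):
        self.e_grid = e_grid
        self._tables: dict[int, np.ndarray] = {}

    def table(self, n: int) -> np.ndarray:
        tab = self._tables.get(n)
        if tab is None:
            k = np.arange(n + 1)[:, None]
            e = np.clip(self.e_grid[None, :], 1e-12, 1 - 1e-12)
            logpmf = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
                      + k * np.log(e) + (n - k) * np.log1p(-e))
            tab = np.exp(logpmf)
            self._tables[n] = tab
        return tab


def _effective_e_weights(model: PDAModel, window_s: float, e_grid: np.ndarray,
                         n_occ: int = 40) -> np.ndarray:
    """Weights over the efficiency grid for the window-averaged efficiency."""
    e1, w1 = model.state1.e_nodes(model.r0)
    e2, w2 = model.state2.e_nodes(model.r0)
    x, wx, a0, a1 = occupancy_distribution(model.k12, model.k21, window_s, n_grid=n_occ)

    vals = []
    wts = []
    # atoms: pure states (quasi-static draw of that state's distance)
    vals.append(e1); wts.append(a1 * w1)
    vals.append(e2); wts.append(a0 * w2)
    # bridge: independent quasi-static draws for both states per window
    ee = (x[:, None, None] * e1[None, :, None]
          + (1 - x)[:, None, None] * e2[None, None, :])
    ww = wx[:, None, None] * w1[None, :, None] * w2[None, None, :]
    vals.append(ee.ravel()); wts.append(ww.ravel())
    v = np.concatenate(vals)
    w = np.concatenate(wts)

    dyn_fraction = 1.0 - sum(f for _, f in model.extra_static)
    w = w * dyn_fraction
    for spec, frac in model.extra_static:
        es, ws = spec.e_nodes(model.r0)
        v = np.concatenate([v, es])
        w = np.concatenate([w, frac * ws])

    # deposit onto the grid with linear interpolation weights
    out = np.zeros(e_grid.size)
    idx = np.clip(np.searchsorted(e_grid, v) - 1, 0, e_grid.size - 2)
    frac = (v - e_grid[idx]) / (e_grid[idx + 1] - e_grid[idx])
    np.add.at(out, idx, w * (1 - frac))
    np.add.at(out, idx + 1, w * frac)
    return out / out.sum()


def pda_predict(
    model: PDAModel,
    window_s: float,
    n_values: np.ndarray,
    n_probs: np.ndarray,
    bin_edges: np.ndarray,
    bg_d_mean: float = 0.0,
    bg_a_mean: float = 0.0,
    cache: Optional[_PredictCache] = None,
    e_grid: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Predicted probability per E_app bin for one window length.

    ``n_values``/``n_probs``: empirical distribution of total (signal +
    background) Dex counts per window.  ``bg_*_mean``: expected background
    counts per window in the donor / acceptor channel, convolved as Poisson.
    """
    if e_grid is None:
        e_grid = np.linspace(0.0, 1.0, 121)
    if cache is None:
        cache = _PredictCache(e_grid)
    w_eff = _effective_e_weights(model, window_s, e_grid)

    def bg_range(mu):
        if mu <= 0:
            return np.array([0]), np.array([1.0])
        hi = int(poisson.ppf(1 - 1e-6, mu)) + 1
        ks = np.arange(hi + 1)
        return ks, poisson.pmf(ks, mu)

    bd, pd_ = bg_range(bg_d_mean)
    ba, pa_ = bg_range(bg_a_mean)

    hist = np.zeros(bin_edges.size - 1)
    # R[k_sig] for each needed signal count level
    rcache: dict[int, np.ndarray] = {}

    def signal_pmf(n_sig: int) -> np.ndarray:
        r = rcache.get(n_sig)
        if r is None:
            r = cache.table(n_sig) @ w_eff
            rcache[n_sig] = r
        return r

    for nv, pn in zip(n_values, n_probs):
        nv = int(nv)
        pk = np.zeros(nv + 1)
        norm = 0.0
        for b_d, p_d in zip(bd, pd_):
            for b_a, p_a in zip(ba, pa_):
                n_sig = nv - b_d - b_a
                if n_sig < 0:
                    continue
                pba = p_d * p_a
                norm += pba
                r = signal_pmf(n_sig)
                pk[b_a: b_a + n_sig + 1] += pba * r
        if norm <= 0:
            continue
        pk /= norm
        e_app = np.arange(nv + 1) / max(nv, 1)
        idx = np.clip(np.digitize(e_app, bin_edges) - 1, 0, hist.size - 1)
        np.add.at(hist, idx, pn * pk)
    return hist


@dataclass
class PDAFitResult:
    model: PDAModel
    relaxation_time_s: float
    chi2_red: float
    params: object
    success: bool


def fit_dynamic_pda(
    datasets: Sequence[dict],
    init: PDAModel,
    bin_edges: Optional[np.ndarray] = None,
    vary_states: bool = True,
    vary_static_fraction: bool = False,
    fixed_params: tuple = (),
    chi2_flag_threshold: float = 3.0,
) -> PDAFitResult:
    """Global chi-square fit of window histograms at several window lengths.

    Each dataset dict carries ``window_s``, ``windows`` (DataFrame from
    :func:`windows_from_bursts`) and optional ``bg_d_mean``/``bg_a_mean``.
    Rates and state parameters are shared across all datasets; the model's
    ``extra_static`` fractions may be varied per fit.  ``fixed_params``
    names parameters (``r1``, ``sig1``, ``r2``) held at their initial
    values — e.g. a state distance known from a structural model.  Pearson
    residuals are used; a fit with reduced chi-square above
    ``chi2_flag_threshold`` is flagged (``success=False``).
    """
    import lmfit

    if len(datasets) < 2:
        raise ValueError("global PDA needs >= 2 window lengths")
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 1.0, 41)
    e_grid = np.linspace(0.0, 1.0, 121)
    cache = _PredictCache(e_grid)

    prepared = []
    for ds in datasets:
        w = ds["windows"]
        nv, counts = np.unique(w["n"].to_numpy(), return_counts=True)
        keep = nv >= 5
        nv, counts = nv[keep], counts[keep]
        n_probs = counts / counts.sum()
        obs, _ = np.histogram(
            w["k"].to_numpy()[np.isin(w["n"], nv)]
            / np.maximum(w["n"].to_numpy()[np.isin(w["n"], nv)], 1),
            bins=bin_edges,
        )
        prepared.append({
            "window_s": ds["window_s"], "n_values": nv, "n_probs": n_probs,
            "obs": obs, "total": obs.sum(),
            "bg_d": ds.get("bg_d_mean", 0.0), "bg_a": ds.get("bg_a_mean", 0.0),
        })

    p = lmfit.Parameters()
    p.add("log_k12", value=np.log10(init.k12), min=-1, max=5)
    p.add("log_k21", value=np.log10(init.k21), min=-1, max=5)
    p.add("r1", value=init.state1.distance or 55.0, min=20, max=150,
          vary=vary_states and "r1" not in fixed_params)
    p.add("sig1", value=init.state1.sigma, min=0.5, max=30,
          vary=vary_states and "sig1" not in fixed_params)
    p.add("r2", value=init.state2.distance or 45.0, min=20, max=150,
          vary=vary_states and "r2" not in fixed_params)
    p.add("sig2", value=init.state2.sigma, min=0.5, max=30, vary=False)
    for i, (_, frac) in enumerate(init.extra_static):
        p.add(f"static_frac_{i}", value=frac, min=0.0, max=0.9,
              vary=vary_static_fraction)

    def build(params) -> PDAModel:
        extra = [(spec, params[f"static_frac_{i}"].value)
                 for i, (spec, _) in enumerate(init.extra_static)]
        return PDAModel(
            state1=PDAStateSpec(distance=params["r1"].value, sigma=params["sig1"].value),
            state2=PDAStateSpec(distance=params["r2"].value, sigma=params["sig2"].value),
            k12=10.0 ** params["log_k12"].value,
            k21=10.0 ** params["log_k21"].value,
            r0=init.r0, extra_static=extra,
        )

    def residuals(params):
        model = build(params)
        res = []
        for ds in prepared:
            prob = pda_predict(model, ds["window_s"], ds["n_values"], ds["n_probs"],
                               bin_edges, ds["bg_d"], ds["bg_a"], cache, e_grid)
            exp = prob * ds["total"]
            res.append((ds["obs"] - exp) / np.sqrt(np.maximum(exp, 1.0)))
        return np.concatenate(res)

    out = lmfit.minimize(residuals, p, method="leastsq", max_nfev=400)
    model = build(out.params)
    chi2_red = float(out.redchi)
    return PDAFitResult(model=model, relaxation_time_s=model.relaxation_time_s,
                        chi2_red=chi2_red, params=out.params,
                        success=bool(out.success) and chi2_red < chi2_flag_threshold)
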