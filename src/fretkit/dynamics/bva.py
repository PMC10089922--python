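"""Burst variance analysis (BVA).

BVA detects FRET dynamics by comparing the standard deviation of the
apparent FRET efficiency within single bursts — computed over consecutive
non-overlapping windows of n donor-excitation photons — to the shot-noise
expectation sqrt(E(1-E)/n) (the semicircle).  A population whose fitted
center lies above the semicircle carries FRET fluctuations slower than the
window duration (typically >~100 us at usual brightness); the excess,
ds_BVA = sigma_0 - sqrt(E_0 (1-E_0)/n), is the BVA dynamic shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..photon_data import DEX, PhotonStream

__all__ = ["BVAResult", "bva_expected_sigma", "bva", "clipped_center_2d"]


def bva_expected_sigma(e_app, n: int):
    """Shot-noise SD of E_app over an n-photon window: sqrt(E(1-E)/n)."""
    if n < 2:
        raise ValueError("photon window must have n >= 2")
    e = np.asarray(e_app, dtype=float)
    out = np.sqrt(np.clip(e * (1.0 - e), 0.0, None) / n)
    return out if out.ndim else float(out)


def clipped_center_2d(x: np.ndarray, y: np.ndarray, n_sigma: float = 2.5,
                      n_iter: int = 5) -> tuple[float, float]:
    """Center of the dominant population of a 2D scatter.

    Iteratively sigma-clipped mean using the Mahalanobis distance — the ML
    center of a single 2D Gaussian, robust to a minority of outliers.
    """
    pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    keep = np.ones(len(pts), dtype=bool)
    for _ in range(n_iter):
        mu = pts[keep].mean(axis=0)
        cov = np.cov(pts[keep].T) + 1e-12 * np.eye(2)
        d = np.einsum("ij,jk,ik->i", pts - mu, np.linalg.inv(cov), pts - mu)
        new = d < n_sigma**2
        if new.sum() < 10 or (new == keep).all():
            break
        keep = new
    mu = pts[keep].mean(axis=0)
    return float(mu[0]), float(mu[1])


@dataclass
class BVAResult:
    """Per-burst E_app and window SD, bin averages and the population center."""

    per_burst: pd.DataFrame        # columns: burst_id, e_app, sigma, n_windows
    bin_centers: np.ndarray        # 0.05-wide E bins over [0, 1]
    bin_sigma: np.ndarray          # average window-SD per bin (NaN when empty)
    center_e: float
    center_sigma: float
    ds: float                      # center_sigma - expected sigma at center_e
    n_window: int
    n_excluded: int                # bursts with < 2 windows


def bva(
    stream: PhotonStream,
    bursts: pd.DataFrame,
    n: int = 5,
    bin_width: float = 0.05,
) -> BVAResult:
    """Burst variance analysis over a burst table.

    For every burst, Dex photons are split into consecutive non-overlapping
    ``n``-photon windows; the apparent efficiency per window is the acceptor
    fraction, and the burst statistic is the Bessel-corrected SD across
    windows.  Bin-averaged SDs (``bin_width`` E bins) and the sigma-clipped
    2D population center are returned together with the BVA dynamic shift.
    """
    if stream.excitation is None:
        raise ValueError("assign_excitation must run before BVA")
    t = stream.times_s
    band = stream.band()
    exc = stream.excitation
    dex_mask = exc == DEX
    t_dex = t[dex_mask]
    a_dex = (band[dex_mask] == 1).astype(np.int8)

    rows = []
    excluded = 0
    for bid, t0, t1 in zip(bursts["burst_id"], bursts["start_s"], bursts["stop_s"]):
        i0 = np.searchsorted(t_dex, t0)
        i1 = np.searchsorted(t_dex, t1, side="right")
        a = a_dex[i0:i1]
        n_win = a.size // n
        if n_win < 2:
            excluded += 1
            continue
        w = a[: n_win * n].reshape(n_win, n).mean(axis=1)
        v = float(np.var(w, ddof=1))
        rows.append((bid, float(a.mean()), float(np.sqrt(v)), v, n_win))
    per_burst = pd.DataFrame(rows, columns=["burst_id", "e_app", "sigma", "var", "n_windows"])

    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_sigma = np.full(centers.size, np.nan)
    if len(per_burst):
        which = np.clip(np.digitize(per_burst["e_app"], edges) - 1, 0, centers.size - 1)
        for b in range(centers.size):
            sel = which == b
            if sel.sum() >= 5:
                bin_sigma[b] = per_burst.loc[sel, "sigma"].mean()

    # population center: average in *variance* domain (the per-burst SD is
    # biased low at few windows; the variance is not), then take the root
    if len(per_burst) >= 10:
        ce, cv = clipped_center_2d(per_burst["e_app"], per_burst["var"])
        cs = float(np.sqrt(max(cv, 0.0)))
    elif len(per_burst):
        ce = float(per_burst["e_app"].mean())
        cs = float(np.sqrt(max(per_burst["var"].mean(), 0.0)))
    else:
        ce = cs = np.nan
    ds = cs - float(bva_expected_sigma(ce, n)) if np.isfinite(ce) else np.nan
    return BVAResult(per_burst=per_burst, bin_centers=centers, bin_sigma=bin_sigma,
                     center_e=ce, center_sigma=cs, ds=ds, n_window=n,
                     n_excluded=excluded)
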