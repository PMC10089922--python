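"""ALEX/PIE correction factors and accurate FRET efficiency / stoichiometry.

Four setup-dependent factors bridge apparent to accurate FRET quantities:
alpha (donor spectral crosstalk into the acceptor channel), delta (direct
acceptor excitation by the donor laser), gamma (acceptor-to-donor ratio of
detection efficiency times fluorescence quantum yield) and beta (excitation
flux normalization).  alpha and delta are read off the donor-only and
acceptor-only populations; beta and gamma come either from a global linear
regression of 1/S versus the alpha/delta-corrected proximity ratio across
two or more FRET populations (the intensity route), or from forcing a
static population onto the static FRET line in the E-vs-lifetime plane
(the lifetime route, pulsed excitation only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CorrectionSet",
    "apparent_E",
    "apparent_S",
    "background_correct",
    "alpha_from_donor_only",
    "delta_from_acceptor_only",
    "fret_signal",
    "beta_gamma_global",
    "gamma_from_static_line",
    "accurate_E_S",
    "efficiency_uncertainty",
    "apply_corrections",
    "subensemble_center",
    "population_center_ES",
]

#: study-level relative gamma uncertainty used when no replicates exist
DEFAULT_RELATIVE_GAMMA_UNCERTAINTY = 0.23


@dataclass
class CorrectionSet:
    """alpha, beta, gamma, delta with uncertainties and provenance."""

    alpha: float
    beta: float
    gamma: float
    delta: float
    d_alpha: float = 0.0
    d_beta: float = 0.0
    d_gamma: Optional[float] = None
    d_delta: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.alpha < 0 or self.delta < 0:
            raise ValueError("alpha and delta must be nonnegative")
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be positive")
        if self.d_gamma is None:
            self.d_gamma = DEFAULT_RELATIVE_GAMMA_UNCERTAINTY * self.gamma

    @classmethod
    def ideal(cls) -> "CorrectionSet":
        return cls(alpha=0.0, beta=1.0, gamma=1.0, delta=0.0, d_gamma=0.0)


def apparent_E(dem_dex, aem_dex):
    """Apparent (raw) FRET efficiency  E_app = I_AemDex / (I_DemDex + I_AemDex).

    Zero denominators yield NaN (burst flagged, not an exception).
    """
    dem_dex = np.asarray(dem_dex, dtype=float)
    aem_dex = np.asarray(aem_dex, dtype=float)
    tot = dem_dex + aem_dex
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(tot > 0, aem_dex / tot, np.nan)
    return out if out.ndim else float(out)


def apparent_S(dem_dex, aem_dex, aem_aex):
    """Apparent stoichiometry  S_app = (DemDex + AemDex) / (DemDex + AemDex + AemAex)."""
    dem_dex = np.asarray(dem_dex, dtype=float)
    aem_dex = np.asarray(aem_dex, dtype=float)
    aem_aex = np.asarray(aem_aex, dtype=float)
    tot = dem_dex + aem_dex + aem_aex
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(tot > 0, (dem_dex + aem_dex) / tot, np.nan)
    return out if out.ndim else float(out)


def background_correct(counts, rates_hz, duration_s):
    """Subtract rate x duration from each channel count.

    ``counts`` and ``rates_hz`` are dicts keyed by channel name
    (``DemDex``, ``AemDex``, ``AemAex``).  Negative results are allowed
    (they carry shot-noise information) and are simply returned.
    """
    duration_s = np.asarray(duration_s, dtype=float)
    return {
        k: np.asarray(counts[k], dtype=float) - rates_hz.get(k, 0.0) * duration_s
        for k in ("DemDex", "AemDex", "AemAex")
        if k in counts
    }


def fret_signal(aem_dex, dem_dex, aem_aex, alpha, delta):
    """Corrected acceptor fluorescence after donor excitation:
    F_A|D = AemDex - alpha * DemDex - delta * AemAex."""
    return (np.asarray(aem_dex, dtype=float)
            - alpha * np.asarray(dem_dex, dtype=float)
            - delta * np.asarray(aem_aex, dtype=float))


def subensemble_center(numerator: np.ndarray, denominator: np.ndarray,
                       n_sigma: float = 2.5, n_iter: int = 6) -> float:
    """Population center of a per-burst count ratio, free of shot-noise bias.

    Per-burst ratios (E_app-like quantities) are Jensen-biased at finite
    photon numbers; the ratio of *summed* counts over the population is not.
    Burst membership is established by sigma-clipping the per-burst ratios
    (isolating the dominant population exactly like a Gaussian fit would),
    then the pooled ratio over the surviving bursts is returned.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    ok = np.isfinite(num) & np.isfinite(den) & (den != 0)
    num, den = num[ok], den[ok]
    r = num / den
    keep = np.ones(r.size, dtype=bool)
    for _ in range(n_iter):
        mu, sd = r[keep].mean(), r[keep].std()
        if sd == 0:
            break
        new = np.abs(r - mu) < n_sigma * sd
        if new.sum() < 10 or (new == keep).all():
            keep = new if new.sum() >= 10 else keep
            break
        keep = new
    return float(num[keep].sum() / den[keep].sum())


class EstimationError(RuntimeError):
    pass


def alpha_from_donor_only(donor_only: "pd.DataFrame", min_bursts: int = 100) -> float:
    """alpha from the donor-only population center:  alpha = <E>/(1 - <E>).

    ``donor_only`` is a burst table (background-corrected counts); the
    population center <E> is the sigma-clipped subensemble ratio of the
    corrected AemDex to total Dex counts.
    """
    if len(donor_only) < min_bursts:
        raise EstimationError(f"need >= {min_bursts} donor-only bursts, got {len(donor_only)}")
    num = donor_only["ii_aem_dex"].to_numpy(float)
    den = num + donor_only["ii_dem_dex"].to_numpy(float)
    center = subensemble_center(num, den)
    return max(center / (1.0 - center), 0.0)


def delta_from_acceptor_only(acceptor_only: "pd.DataFrame", min_bursts: int = 100) -> float:
    """delta from the acceptor-only population center:  delta = <S>/(1 - <S>)."""
    if len(acceptor_only) < min_bursts:
        raise EstimationError(f"need >= {min_bursts} acceptor-only bursts, got {len(acceptor_only)}")
    dex = (acceptor_only["ii_dem_dex"].to_numpy(float)
           + acceptor_only["ii_aem_dex"].to_numpy(float))
    tot = dex + acceptor_only["ii_aem_aex"].to_numpy(float)
    center = subensemble_center(dex, tot)
    return max(center / (1.0 - center), 0.0)


def population_center_ES(bursts: "pd.DataFrame", corrections: CorrectionSet) -> tuple[float, float]:
    """Shot-noise-free (E, S) center of one FRET population.

    Applies the full correction set to the sigma-clipped pooled counts of
    the population (subensemble estimate).  With gamma = beta = 1 and only
    alpha/delta set, this yields the (E_PR, S_PR) centers that feed
    :func:`beta_gamma_global`.
    """
    dd = bursts["ii_dem_dex"].to_numpy(float)
    ad = bursts["ii_aem_dex"].to_numpy(float)
    aa = bursts["ii_aem_aex"].to_numpy(float)
    c = corrections
    f_ad = fret_signal(ad, dd, aa, c.alpha, c.delta)
    dex = c.gamma * dd + f_ad
    with np.errstate(divide="ignore", invalid="ignore"):
        e_b = np.where(dex != 0, f_ad / dex, np.nan)
    keep = np.isfinite(e_b)
    r = e_b[keep]
    kmask = np.ones(r.size, bool)
    for _ in range(6):
        mu, sd = r[kmask].mean(), r[kmask].std()
        if sd == 0:
            break
        new = np.abs(r - mu) < 2.5 * sd
        if new.sum() < 10 or (new == kmask).all():
            kmask = new if new.sum() >= 10 else kmask
            break
        kmask = new
    idx = np.flatnonzero(keep)[kmask]
    e = float(f_ad[idx].sum() / dex[idx].sum())
    s = float(dex[idx].sum() / (dex[idx].sum() + aa[idx].sum() / c.beta))
    return e, s


def beta_gamma_global(population_centers: Sequence[tuple[float, float]]):
    """Global beta/gamma from >=2 FRET-population centers (Lee-type regression).

    Each center is ``(E_PR, S_PR)``: the population's alpha/delta- and
    background-corrected proximity ratio and stoichiometry (gamma = beta = 1).
    1/S is linear in E_PR with intercept Omega = 1 + beta*gamma and slope
    Sigma = beta*(1 - gamma), hence gamma = (Omega - 1)/(Omega + Sigma - 1)
    and beta = Omega + Sigma - 1.  Returns ``(beta, gamma, diagnostics)``.
    """
    centers = np.asarray(population_centers, dtype=float)
    if centers.ndim != 2 or centers.shape[0] < 2:
        raise ValueError("need at least two (E, S) population centers; "
                         "with a single static population use the lifetime route")
    e = centers[:, 0]
    s = centers[:, 1]
    if np.ptp(e) < 0.1:
        warnings.warn("population centers span |dE| < 0.1; the 1/S-vs-E regression "
                      "is ill-conditioned", stacklevel=2)
    coef = np.polyfit(e, 1.0 / s, 1)  # unweighted LSQ across 2-6 centers
    slope, intercept = float(coef[0]), float(coef[1])
    denom = intercept + slope - 1.0
    if abs(denom) < 1e-12 or abs(intercept - 1.0) < 1e-12:
        # degenerate flat line at 1/S = 2: ideal dyes
        return 1.0, 1.0, {"intercept": intercept, "slope": slope, "degenerate": True}
    gamma = (intercept - 1.0) / denom
    beta = denom
    resid = 1.0 / s - (intercept + slope * e)
    diag = {"intercept": intercept, "slope": slope,
            "residual_norm": float(np.sqrt(np.sum(resid**2))), "degenerate": False}
    return beta, gamma, diag


def gamma_from_static_line(
    e_pr_center: float,
    tau_center_ns: float,
    tau_d0_ns: float,
    static_line=None,
    ds_threshold: float = 0.05,
):
    """gamma forcing a static population onto the static FRET line.

    ``e_pr_center`` is the alpha/delta-corrected proximity-ratio center and
    ``tau_center_ns`` the population's fluorescence-weighted donor lifetime.
    The corrected efficiency E(gamma) = E_PR / (gamma (1-E_PR) + E_PR) is
    matched to the (optionally linker-corrected) static line at tau_center.
    A warning is recorded when the implied dynamic shift exceeds
    ``ds_threshold`` (dynamic sample suspected).  Returns (gamma, warnings).
    """
    if static_line is None:
        e_target = 1.0 - tau_center_ns / tau_d0_ns
    else:
        e_target = float(static_line(tau_center_ns))
    notes = []
    e_target = min(max(e_target, 1e-6), 1 - 1e-6)
    e_pr = min(max(e_pr_center, 1e-6), 1 - 1e-6)
    # E(gamma) = e_pr / (gamma*(1-e_pr) + e_pr)  ==  e_target  (exact inversion)
    gamma = e_pr * (1.0 - e_target) / (e_target * (1.0 - e_pr))
    e_corr = e_pr / (gamma * (1 - e_pr) + e_pr)
    if abs(e_corr - e_target) > ds_threshold:
        notes.append("population does not reach the static line: dynamic sample?")
    return gamma, notes


def accurate_E_S(dem_dex, aem_dex, aem_aex, corrections: CorrectionSet):
    """Accurate FRET efficiency and stoichiometry from corrected counts.

    E = F_A|D / (gamma I_DemDex + F_A|D);
    S = (gamma I_DemDex + F_A|D) / (gamma I_DemDex + F_A|D + I_AemAex / beta).
    Counts must already be background-corrected.  Zero denominators give NaN.
    """
    c = corrections
    f_ad = fret_signal(aem_dex, dem_dex, aem_aex, c.alpha, c.delta)
    gd = c.gamma * np.asarray(dem_dex, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom_e = gd + f_ad
        e = np.where(np.abs(denom_e) > 0, f_ad / denom_e, np.nan)
        denom_s = denom_e + np.asarray(aem_aex, dtype=float) / c.beta
        s = np.where(np.abs(denom_s) > 0, denom_e / denom_s, np.nan)
    if np.ndim(e) == 0:
        return float(e), float(s)
    return e, s


def efficiency_uncertainty(e, gamma: float, d_gamma: float):
    """Gamma-driven FRET-efficiency uncertainty  dE = E (1-E) dgamma/gamma."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    e = np.asarray(e, dtype=float)
    out = e * (1.0 - e) * (d_gamma / gamma)
    return out if out.ndim else float(out)


def apply_corrections(bursts: pd.DataFrame, corrections: CorrectionSet) -> pd.DataFrame:
    """Fill accurate E and S columns of a burst table (in place copy).

    Expects background-corrected columns ``ii_dem_dex``, ``ii_aem_dex``,
    ``ii_aem_aex`` (see :mod:`fretkit.bursts`).
    """
    out = bursts.copy()
    e, s = accurate_E_S(out["ii_dem_dex"].to_numpy(), out["ii_aem_dex"].to_numpy(),
                        out["ii_aem_aex"].to_numpy(), corrections)
    out["E"] = e
    out["S"] = s
    return out
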