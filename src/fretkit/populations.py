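"""FRET-efficiency histograms, Gaussian fitting, consensus statistics and
Forster distance conversion.

Mean FRET efficiencies are always reported as Gaussian component means.
Fitting is unbinned maximum likelihood by default (Gaussian mixture); a
binned least-squares route exists for histogrammed input.  Cross-replicate
consensus statistics mirror multi-laboratory reporting: per-replicate
means, grand mean and SD, and paired condition differences whose SD is the
SD of the per-replicate differences (so shared systematic offsets cancel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GaussianFit",
    "ConsensusStats",
    "DistanceEstimate",
    "fit_gaussians",
    "consensus",
    "efficiency_to_distance",
    "distance_to_efficiency",
]

DEFAULT_BIN_WIDTH = 0.025
DEFAULT_RANGE = (-0.1, 1.1)


@dataclass
class GaussianFit:
    """Gaussian mixture fit of an efficiency distribution (components sorted by mean)."""

    means: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray
    fit_range: tuple[float, float]
    residual_norm: float = np.nan
    warnings_: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.means)


def fit_gaussians(
    e_values: np.ndarray,
    n_components: int = 1,
    init_means: Optional[Sequence[float]] = None,
    fit_range: tuple[float, float] = DEFAULT_RANGE,
    seed: int = 0,
) -> GaussianFit:
    """Unbinned ML Gaussian-mixture fit of burst efficiencies.

    ``fit_range`` restricts the data (e.g. to exclude a donor-only peak
    near zero).  Components are returned ordered by mean; near-degenerate
    components (|dmean| < sigma/2) raise a warning in ``warnings_``.
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    v = np.asarray(e_values, dtype=float)
    v = v[np.isfinite(v)]
    v = v[(v >= fit_range[0]) & (v <= fit_range[1])]
    notes = []
    if v.size < 200:
        notes.append(f"only {v.size} bursts in fit range; >=200 recommended")
    if np.ptp(v) < 1e-12:
        # single point mass: sigma floored at the display bin width
        return GaussianFit(means=np.array([v[0] if v.size else np.nan]),
                           sigmas=np.array([DEFAULT_BIN_WIDTH]),
                           weights=np.array([1.0]), fit_range=fit_range,
                           warnings_=notes + ["degenerate input: sigma floored at bin width"])
    if n_components == 1:
        mu, sd = float(v.mean()), float(v.std(ddof=1))
        return GaussianFit(means=np.array([mu]), sigmas=np.array([max(sd, 1e-6)]),
                           weights=np.array([1.0]), fit_range=fit_range, warnings_=notes)

    from sklearn.mixture import GaussianMixture

    means_init = None
    if init_means is not None:
        means_init = np.asarray(init_means, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(n_components=n_components, covariance_type="full",
                         means_init=means_init, n_init=1 if means_init is not None else 5,
                         random_state=seed, max_iter=500)
    gm.fit(v.reshape(-1, 1))
    if not gm.converged_:
        raise RuntimeError(f"Gaussian mixture did not converge (lower bound {gm.lower_bound_:.3g})")
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sigmas = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    for i in range(len(means) - 1):
        if means[i + 1] - means[i] < 0.5 * max(sigmas[i], sigmas[i + 1]):
            notes.append(f"components {i} and {i+1} overlap (|dmean| < sigma/2)")
    return GaussianFit(means=means, sigmas=sigmas, weights=weights,
                       fit_range=fit_range, warnings_=notes)


@dataclass
class ConsensusStats:
    """Cross-replicate mean/SD plus paired condition differences."""

    replicate_means: np.ndarray
    grand_mean: float
    sd: float
    paired_differences: Optional[np.ndarray] = None
    difference_mean: Optional[float] = None
    difference_sd: Optional[float] = None


def consensus(
    replicate_means: Sequence[float],
    paired_condition_means: Optional[Sequence[float]] = None,
) -> ConsensusStats:
    """Grand mean/SD over replicates; paired differences if a second
    condition is given (element i of both sequences must come from the same
    replicate — the difference SD is the SD of per-replicate differences,
    which cancels shared systematic offsets exactly)."""
    a = np.asarray(replicate_means, dtype=float)
    if a.size < 2:
        raise ValueError("need >= 2 replicates")
    out = ConsensusStats(replicate_means=a, grand_mean=float(a.mean()),
                         sd=float(a.std(ddof=1)))
    if paired_condition_means is not None:
        b = np.asarray(paired_condition_means, dtype=float)
        if b.shape != a.shape:
            raise ValueError("paired condition means must align with replicates")
        dif = b - a
        out.paired_differences = dif
        out.difference_mean = float(dif.mean())
        out.difference_sd = float(dif.std(ddof=1))
    return out


@dataclass
class DistanceEstimate:
    """FRET-averaged distance with first-order uncertainty contributions (Angstrom)."""

    r_mean: float
    dr_from_de: float
    dr_from_dr0: float
    r0: float


def efficiency_to_distance(e: float, r0: float, de: float = 0.0, dr0: float = 0.0) -> DistanceEstimate:
    """R<E> = R0 (1/E - 1)^(1/6) with propagated dE and dR0 contributions."""
    if not 0.0 < e < 1.0:
        raise ValueError(f"efficiency must lie in (0, 1), got {e}")
    if r0 <= 0:
        raise ValueError("Forster radius must be positive")
    r = r0 * (1.0 / e - 1.0) ** (1.0 / 6.0)
    # dR/dE = -R / (6 E (1-E))
    dr_de = abs(r / (6.0 * e * (1.0 - e))) * de
    dr_dr0 = (r / r0) * dr0
    return DistanceEstimate(r_mean=float(r), dr_from_de=float(dr_de),
                            dr_from_dr0=float(dr_dr0), r0=r0)


def distance_to_efficiency(r: float, r0: float) -> float:
    """Inverse of :func:`efficiency_to_distance`: E = 1/(1 + (R/R0)^6)."""
    return 1.0 / (1.0 + (r / r0) ** 6)
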