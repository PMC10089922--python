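"""Background estimation, burst search, selection and summary statistics.

Burst identification uses the all-photon sliding-window criterion: a photon
belongs to a burst when the local rate estimated over ``m`` consecutive
photons exceeds ``F`` times the total background rate.  Consecutive in-burst
photons are merged and bursts shorter than ``L_min`` photons discarded.
Background rates per (emission band | excitation label) channel come from an
exponential fit to the tail of the inter-photon delay distribution, which is
insensitive to the burst contribution at short delays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .photon_data import AEX, DEX, PhotonStream
from .corrections import apparent_E, apparent_S

__all__ = [
    "BackgroundModel",
    "BurstSummary",
    "estimate_background",
    "search_bursts",
    "select_bursts",
    "burst_summary",
    "SelectionThresholds",
]

#: burst-table column names (exported as CSV by the CLI)
BURST_COLUMNS = [
    "burst_id", "start_s", "stop_s", "duration_ms",
    "i_dem_dex", "i_aem_dex", "i_aem_aex",
    "ii_dem_dex", "ii_aem_dex", "ii_aem_aex",
    "e_app", "s_app",
]


@dataclass
class BackgroundModel:
    """Per-channel background rates (Hz) with the estimation method tag."""

    rates_hz: dict[str, float]
    method: str = "delay-tail-mle"

    def __post_init__(self):
        for k, v in self.rates_hz.items():
            if v < 0:
                raise ValueError(f"negative background rate for {k}")

    @property
    def total_hz(self) -> float:
        return float(sum(self.rates_hz.values()))


def _delay_tail_rate(times_s: np.ndarray) -> float:
    """MLE of the Poisson rate from the exponential tail of inter-photon delays.

    Delays above a threshold (set iteratively to ~2x the current mean delay)
    are exponential with the background rate even when bursts are present;
    the truncated-exponential MLE is 1/(mean(d) - threshold).
    """
    if times_s.size < 100:
        warnings.warn(f"only {times_s.size} photons in channel; background set to 0",
                      stacklevel=3)
        return 0.0
    d = np.diff(times_s)
    d = d[d > 0]
    if d.size < 50:
        return 0.0
    rate = 1.0 / d.mean()
    for _ in range(4):
        thr = 2.0 / rate
        tail = d[d > thr]
        if tail.size < 20:
            break
        new = 1.0 / (tail.mean() - thr)
        if abs(new - rate) < 1e-3 * rate:
            rate = new
            break
        rate = new
    return float(rate)


def estimate_background(stream: PhotonStream) -> BackgroundModel:
    """Background rates for DemDex / AemDex / AemAex via delay-tail fits."""
    if stream.excitation is None:
        raise ValueError("assign_excitation must run before background estimation")
    t = stream.times_s
    band = stream.band()
    exc = stream.excitation
    rates = {}
    for key, mask in (
        ("DemDex", (band == 0) & (exc == DEX)),
        ("AemDex", (band == 1) & (exc == DEX)),
        ("AemAex", (band == 1) & (exc == AEX)),
    ):
        # rate within the channel's own live windows: scale by duty cycle
        rates[key] = _delay_tail_rate(t[mask])
    return BackgroundModel(rates_hz=rates)


def search_bursts(
    stream: PhotonStream,
    background: BackgroundModel,
    m: int = 10,
    F: float = 6.0,
    l_min: int = 30,
) -> pd.DataFrame:
    """All-photon sliding-window burst search.

    A photon is *in a burst* when the ``m``-photon window starting at it is
    shorter than ``m / (F x total background rate)``; runs of in-burst
    photons are merged and bursts with fewer than ``l_min`` photons dropped.
    Returns the burst table with raw channel counts, apparent E and S
    (background-corrected counts are filled with the per-burst
    duration x rate subtraction).
    """
    if m < 2:
        raise ValueError("window size m must be >= 2")
    if stream.excitation is None:
        raise ValueError("assign_excitation must run before burst search")
    t = stream.times_s
    n = t.size
    if n < m:
        return pd.DataFrame(columns=BURST_COLUMNS)
    rate_thr = F * background.total_hz
    if rate_thr <= 0:
        # zero background: any m-photon cluster denser than 1/0 never triggers;
        # fall back to a practical ceiling so isolated clusters are still found
        rate_thr = m / (t[-1] - t[0] + 1e-9)
    max_span = m / rate_thr
    span = t[m - 1:] - t[: n - m + 1]
    seed = span < max_span  # photon i starts a dense window
    in_burst = np.zeros(n, dtype=bool)
    # mark all photons covered by any dense window via run-length trick
    starts = np.flatnonzero(seed)
    if starts.size:
        delta = np.zeros(n + 1, dtype=np.int64)
        np.add.at(delta, starts, 1)
        np.add.at(delta, np.minimum(starts + m, n), -1)
        in_burst = np.cumsum(delta[:-1]) > 0

    edges = np.diff(in_burst.astype(np.int8))
    b_starts = np.flatnonzero(edges == 1) + 1
    b_stops = np.flatnonzero(edges == -1) + 1
    if in_burst[0]:
        b_starts = np.r_[0, b_starts]
    if in_burst[-1]:
        b_stops = np.r_[b_stops, n]

    band = stream.band()
    exc = stream.excitation
    rows = []
    bid = 0
    # edge photons separated from the burst core by more than half the
    # dense-window mean delay are background picked up by window padding;
    # trimming them removes a systematic excess of background counts over
    # the duration x rate subtraction (the padding photons are *selected*
    # for short delays, so their density exceeds the average rate)
    trim_thr = max_span / (2 * m)
    for i0, i1 in zip(b_starts, b_stops):
        while i1 - i0 > 2:
            if t[i0 + 1] - t[i0] > trim_thr:
                i0 += 1
            elif t[i1 - 1] - t[i1 - 2] > trim_thr:
                i1 -= 1
            else:
                break
        if i1 - i0 < l_min:
            continue
        b = band[i0:i1]
        x = exc[i0:i1]
        dd = int(np.count_nonzero((b == 0) & (x == DEX)))
        ad = int(np.count_nonzero((b == 1) & (x == DEX)))
        aa = int(np.count_nonzero((b == 1) & (x == AEX)))
        dur = t[i1 - 1] - t[i0]
        rows.append((bid, t[i0], t[i1 - 1], dur * 1e3, dd, ad, aa))
        bid += 1
    df = pd.DataFrame(rows, columns=["burst_id", "start_s", "stop_s", "duration_ms",
                                     "i_dem_dex", "i_aem_dex", "i_aem_aex"])
    dur_s = df["duration_ms"].to_numpy() * 1e-3
    for raw, cor, key in (("i_dem_dex", "ii_dem_dex", "DemDex"),
                          ("i_aem_dex", "ii_aem_dex", "AemDex"),
                          ("i_aem_aex", "ii_aem_aex", "AemAex")):
        df[cor] = df[raw].to_numpy(float) - background.rates_hz.get(key, 0.0) * dur_s
    df["e_app"] = apparent_E(df["i_dem_dex"], df["i_aem_dex"])
    df["s_app"] = apparent_S(df["i_dem_dex"], df["i_aem_dex"], df["i_aem_aex"])
    # background-corrected proximity ratio / stoichiometry: the inputs to
    # correction-factor determination and species selection
    df["e_pr"] = apparent_E(df["ii_dem_dex"], df["ii_aem_dex"])
    df["s_pr"] = apparent_S(df["ii_dem_dex"], df["ii_aem_dex"], df["ii_aem_aex"])
    return df


@dataclass(frozen=True)
class SelectionThresholds:
    """Stoichiometry-based species gates (all configurable)."""

    donor_only_min_s: float = 0.8
    acceptor_only_max_s: float = 0.2
    fret_s_range: tuple[float, float] = (0.25, 0.75)
    min_aex_counts: int = 10

    def __post_init__(self):
        lo, hi = self.fret_s_range
        if not (self.acceptor_only_max_s <= lo < hi <= self.donor_only_min_s):
            raise ValueError("selection thresholds overlap")


def select_bursts(bursts: pd.DataFrame, thresholds: SelectionThresholds | None = None):
    """Partition bursts into (FRET pair, donor-only, acceptor-only) subsets.

    Uses background-corrected stoichiometry: donor-only at high S, acceptor-
    only at low S, FRET pairs at intermediate S with a minimum Aex signal.
    The three subsets are disjoint by construction.
    """
    th = thresholds or SelectionThresholds()
    s = apparent_S(bursts["ii_dem_dex"], bursts["ii_aem_dex"], bursts["ii_aem_aex"])
    s = np.asarray(s, dtype=float)
    donor_only = bursts[s > th.donor_only_min_s]
    acceptor_only = bursts[s < th.acceptor_only_max_s]
    lo, hi = th.fret_s_range
    fret = bursts[(s >= lo) & (s <= hi)
                  & (bursts["ii_aem_aex"].to_numpy() >= th.min_aex_counts)]
    return fret, donor_only, acceptor_only


@dataclass
class BurstSummary:
    n_bursts: int
    mean_rate_khz: float
    sd_rate_khz: float
    mean_photons: float
    sd_photons: float
    mean_duration_ms: float
    sd_duration_ms: float
    corr_photons_duration: float
    corr_rate_duration: float
    corr_rate_photons: float


def burst_summary(bursts: pd.DataFrame) -> BurstSummary:
    """Moments and Pearson correlations of rate / photons / duration."""
    if len(bursts) < 2:
        raise ValueError("need at least two bursts to summarize")
    photons = (bursts["i_dem_dex"] + bursts["i_aem_dex"] + bursts["i_aem_aex"]).to_numpy(float)
    dur = bursts["duration_ms"].to_numpy(float)
    rate = photons / dur  # kHz

    def corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    return BurstSummary(
        n_bursts=len(bursts),
        mean_rate_khz=float(rate.mean()), sd_rate_khz=float(rate.std()),
        mean_photons=float(photons.mean()), sd_photons=float(photons.std()),
        mean_duration_ms=float(dur.mean()), sd_duration_ms=float(dur.std()),
        corr_photons_duration=corr(photons, dur),
        corr_rate_duration=corr(rate, dur),
        corr_rate_photons=corr(rate, photons),
    )
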