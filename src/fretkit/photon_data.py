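"""Photon-stream data model and I/O.

Diffusion-based confocal smFRET measurements record, for every detected
photon, a coarse arrival time (the *macrotime*, in integer ticks of a sync
clock), the detector it arrived on, and — for pulsed excitation — a TCSPC
*microtime* measured relative to the laser pulse.  Alternating excitation
(µs-ALEX on the macrotime axis, or PIE/ns-ALEX on the microtime axis)
interleaves donor and acceptor excitation so that every photon can be
attributed to one excitation period.  This module holds the in-memory
containers for such streams, the excitation-period assignment, the
three-channel counting used throughout the intensity analysis, and a
minimal Photon-HDF5 reader/writer plus a plain-text (CSV) fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import h5py

__all__ = [
    "ChannelMap",
    "ExcitationScheme",
    "PhotonStream",
    "FormatError",
    "assign_excitation",
    "channel_counts",
    "read_photon_hdf5",
    "write_photon_hdf5",
    "read_photon_csv",
    "write_photon_csv",
]

#: excitation labels stored per photon (int8)
UNASSIGNED = 0
DEX = 1
AEX = 2
OUTSIDE = -1

_LABEL_NAMES = {UNASSIGNED: "unassigned", DEX: "Dex", AEX: "Aex", OUTSIDE: "outside"}


class FormatError(ValueError):
    """Raised when a file misses a mandatory field or violates an invariant."""


@dataclass(frozen=True)
class ChannelMap:
    """detector_id -> (spectral band, polarization).

    band is ``"donor"`` or ``"acceptor"``; polarization is ``"parallel"``,
    ``"perpendicular"`` or ``"unpolarized"``.
    """

    channels: dict[int, tuple[str, str]]

    def __post_init__(self):
        bands = {b for b, _ in self.channels.values()}
        if "donor" not in bands or "acceptor" not in bands:
            raise ValueError("channel map needs at least one donor and one acceptor detector")
        for det, (band, pol) in self.channels.items():
            if band not in ("donor", "acceptor"):
                raise ValueError(f"unknown spectral band {band!r} for detector {det}")
            if pol not in ("parallel", "perpendicular", "unpolarized"):
                raise ValueError(f"unknown polarization {pol!r} for detector {det}")

    def detectors(self, band: str | None = None, polarization: str | None = None) -> list[int]:
        out = []
        for det, (b, p) in self.channels.items():
            if band is not None and b != band:
                continue
            if polarization is not None and p != polarization:
                continue
            out.append(det)
        return sorted(out)

    def band_of(self) -> dict[int, str]:
        return {det: b for det, (b, _) in self.channels.items()}

    @classmethod
    def simple(cls) -> "ChannelMap":
        """Two unpolarized detectors: 0 = donor, 1 = acceptor."""
        return cls({0: ("donor", "unpolarized"), 1: ("acceptor", "unpolarized")})

    @classmethod
    def polarized(cls) -> "ChannelMap":
        """Four-detector MFD layout (donor/acceptor x parallel/perpendicular)."""
        return cls(
            {
                0: ("donor", "parallel"),
                1: ("donor", "perpendicular"),
                2: ("acceptor", "parallel"),
                3: ("acceptor", "perpendicular"),
            }
        )


@dataclass(frozen=True)
class ExcitationScheme:
    """Alternation layout assigning photons to Dex/Aex periods.

    ``mode="usalex"``: windows are ``(start, stop)`` in macrotime ticks within
    the alternation ``period`` (ticks).  ``mode="pie"``: windows are
    ``(start, stop)`` in microtime bins within the TCSPC range.
    Windows must be disjoint and fit inside one period.
    """

    mode: str
    period: Optional[int] = None
    dex_window: tuple[int, int] = (0, 0)
    aex_window: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if self.mode not in ("usalex", "pie"):
            raise ValueError(f"unknown excitation mode {self.mode!r}")
        d0, d1 = self.dex_window
        a0, a1 = self.aex_window
        if not (d0 < d1 and a0 < a1):
            raise ValueError("excitation windows must be non-empty (start < stop)")
        if not (d1 <= a0 or a1 <= d0):
            raise ValueError("Dex and Aex windows overlap")
        if self.mode == "usalex":
            if self.period is None:
                raise ValueError("usALEX scheme needs an alternation period")
            if max(d1, a1) > self.period:
                raise ValueError("windows exceed the alternation period")


@dataclass
class PhotonStream:
    """Timestamped photons with channel labels and optional microtimes.

    macrotimes are integer clock ticks (nondecreasing); ``clock_rate`` is in
    Hz so ``macrotimes / clock_rate`` are seconds.  microtimes, when present,
    are TCSPC bin indices with ``microtime_resolution_ps`` bin width and
    ``microtime_range`` total bins (one laser period).
    """

    macrotimes: np.ndarray
    clock_rate: float
    detectors: np.ndarray
    channel_map: ChannelMap
    microtimes: Optional[np.ndarray] = None
    microtime_resolution_ps: Optional[float] = None
    microtime_range: Optional[int] = None
    excitation: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.macrotimes = np.asarray(self.macrotimes, dtype=np.int64)
        self.detectors = np.asarray(self.detectors, dtype=np.int16)
        if self.macrotimes.shape != self.detectors.shape:
            raise ValueError("macrotimes and detectors must have equal length")
        if self.macrotimes.size and np.any(np.diff(self.macrotimes) < 0):
            raise FormatError("macrotimes must be nondecreasing")
        known = set(self.channel_map.channels)
        present = set(np.unique(self.detectors).tolist())
        if not present <= known:
            raise FormatError(f"detector ids {sorted(present - known)} missing from channel map")
        if self.microtimes is not None:
            self.microtimes = np.asarray(self.microtimes)
            if self.microtimes.shape != self.macrotimes.shape:
                raise ValueError("microtimes must align with macrotimes")
            if self.microtime_range is not None and self.microtimes.size:
                if self.microtimes.max(initial=0) >= self.microtime_range:
                    raise FormatError("microtimes exceed the TCSPC period")
        if self.excitation is not None:
            self.excitation = np.asarray(self.excitation, dtype=np.int8)
            if self.excitation.shape != self.macrotimes.shape:
                raise ValueError("excitation labels must align with photons")

    # -- convenience -------------------------------------------------------
    @property
    def n_photons(self) -> int:
        return int(self.macrotimes.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.macrotimes / self.clock_rate

    @property
    def duration_s(self) -> float:
        if "duration_s" in self.meta:
            return float(self.meta["duration_s"])
        if self.n_photons == 0:
            return 0.0
        return float((self.macrotimes[-1] - self.macrotimes[0]) / self.clock_rate)

    def band(self) -> np.ndarray:
        """Per-photon spectral band: 0 = donor, 1 = acceptor."""
        lut_size = max(self.channel_map.channels) + 1
        lut = np.zeros(lut_size, dtype=np.int8)
        for det, (b, _) in self.channel_map.channels.items():
            lut[det] = 0 if b == "donor" else 1
        return lut[self.detectors]

    def select(self, mask: np.ndarray) -> "PhotonStream":
        return replace(
            self,
            macrotimes=self.macrotimes[mask],
            detectors=self.detectors[mask],
            microtimes=None if self.microtimes is None else self.microtimes[mask],
            excitation=None if self.excitation is None else self.excitation[mask],
            meta=dict(self.meta),
        )


def assign_excitation(stream: PhotonStream, scheme: ExcitationScheme) -> PhotonStream:
    """Label every photon Dex or Aex according to the alternation scheme.

    Photons outside all windows are flagged (label ``OUTSIDE``) and are
    excluded from channel counts downstream.  Returns a new stream.
    """
    if scheme.mode == "usalex":
        phase = stream.macrotimes % scheme.period
        basis = phase
    else:
        if stream.microtimes is None:
            raise ValueError("PIE excitation assignment requires microtimes")
        basis = stream.microtimes
    labels = np.full(stream.n_photons, OUTSIDE, dtype=np.int8)
    d0, d1 = scheme.dex_window
    a0, a1 = scheme.aex_window
    labels[(basis >= d0) & (basis < d1)] = DEX
    labels[(basis >= a0) & (basis < a1)] = AEX
    out = replace(stream, excitation=labels, meta=dict(stream.meta))
    out.meta["excitation_scheme"] = scheme
    return out


def channel_counts(
    stream: PhotonStream, interval: Optional[tuple[float, float]] = None
) -> dict[str, int]:
    """Counts per (emission band | excitation label) in a time interval.

    ``interval`` is ``(start_s, stop_s)`` in seconds (half-open); ``None``
    counts the whole stream.  Keys: ``DemDex``, ``AemDex``, ``AemAex``,
    ``DemAex`` (retained but unused by the intensity formulas) and
    ``outside`` for flagged photons.
    """
    if stream.excitation is None:
        raise ValueError("assign_excitation must run before counting")
    if interval is None:
        sel = slice(None)
    else:
        t0, t1 = interval
        i0 = np.searchsorted(stream.macrotimes, int(round(t0 * stream.clock_rate)), "left")
        i1 = np.searchsorted(stream.macrotimes, int(round(t1 * stream.clock_rate)), "left")
        sel = slice(i0, i1)
    band = stream.band()[sel]
    exc = stream.excitation[sel]
    out = {
        "DemDex": int(np.count_nonzero((band == 0) & (exc == DEX))),
        "AemDex": int(np.count_nonzero((band == 1) & (exc == DEX))),
        "AemAex": int(np.count_nonzero((band == 1) & (exc == AEX))),
        "DemAex": int(np.count_nonzero((band == 0) & (exc == AEX))),
        "outside": int(np.count_nonzero(exc == OUTSIDE)),
    }
    return out


# ---------------------------------------------------------------------------
# Photon-HDF5 (minimal subset)
# ---------------------------------------------------------------------------

def write_photon_hdf5(stream: PhotonStream, path) -> None:
    """Write the minimal Photon-HDF5 subset used by this package.

    Layout: ``photon_data/timestamps``, ``photon_data/detectors``,
    ``photon_data/timestamps_specs/timestamps_unit`` and, when microtimes are
    present, ``photon_data/nanotimes`` with ``nanotimes_specs``.  The channel
    map is stored as parallel arrays under ``setup/``.
    """
    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        g.create_dataset("timestamps", data=stream.macrotimes)
        g.create_dataset("detectors", data=stream.detectors)
        g.create_group("timestamps_specs").create_dataset(
            "timestamps_unit", data=1.0 / stream.clock_rate
        )
        if stream.microtimes is not None:
            g.create_dataset("nanotimes", data=stream.microtimes)
            ns = g.create_group("nanotimes_specs")
            ns.create_dataset("tcspc_unit", data=stream.microtime_resolution_ps * 1e-12)
            ns.create_dataset("tcspc_num_bins", data=stream.microtime_range or 0)
        setup = f.create_group("setup")
        dets = sorted(stream.channel_map.channels)
        setup.create_dataset("detector_ids", data=np.array(dets))
        setup.create_dataset(
            "detector_bands",
            data=np.array([stream.channel_map.channels[d][0] for d in dets], dtype="S16"),
        )
        setup.create_dataset(
            "detector_polarizations",
            data=np.array([stream.channel_map.channels[d][1] for d in dets], dtype="S16"),
        )
        if "duration_s" in stream.meta:
            setup.create_dataset("duration_s", data=float(stream.meta["duration_s"]))


def read_photon_hdf5(path) -> PhotonStream:
    """Read a stream written by :func:`write_photon_hdf5`.

    Missing mandatory groups raise :class:`FormatError` naming the field;
    unsorted timestamps are rejected.
    """
    with h5py.File(path, "r") as f:
        if "photon_data" not in f:
            raise FormatError("missing mandatory group 'photon_data'")
        g = f["photon_data"]
        for name in ("timestamps", "detectors"):
            if name not in g:
                raise FormatError(f"missing mandatory field 'photon_data/{name}'")
        if "timestamps_specs" not in g or "timestamps_unit" not in g["timestamps_specs"]:
            raise FormatError("missing mandatory field 'photon_data/timestamps_specs/timestamps_unit'")
        macrotimes = g["timestamps"][()]
        detectors = g["detectors"][()]
        clock_rate = 1.0 / float(g["timestamps_specs/timestamps_unit"][()])
        microtimes = res = nbins = None
        if "nanotimes" in g:
            microtimes = g["nanotimes"][()]
            res = float(g["nanotimes_specs/tcspc_unit"][()]) * 1e12
            nbins = int(g["nanotimes_specs/tcspc_num_bins"][()]) or None
        if "setup" in f and "detector_ids" in f["setup"]:
            s = f["setup"]
            cmap = ChannelMap(
                {
                    int(d): (b.decode(), p.decode())
                    for d, b, p in zip(
                        s["detector_ids"][()],
                        s["detector_bands"][()],
                        s["detector_polarizations"][()],
                    )
                }
            )
        else:
            cmap = ChannelMap.simple()
        meta = {}
        if "setup" in f and "duration_s" in f["setup"]:
            meta["duration_s"] = float(f["setup/duration_s"][()])
    return PhotonStream(
        macrotimes=macrotimes,
        clock_rate=clock_rate,
        detectors=detectors,
        channel_map=cmap,
        microtimes=microtimes,
        microtime_resolution_ps=res,
        microtime_range=nbins,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# tabular text fallback
# ---------------------------------------------------------------------------

def write_photon_csv(stream: PhotonStream, path) -> None:
    """One photon per row: macrotime_ticks, detector_id, microtime_bin.

    Header comment lines carry the clock rate, TCSPC specs and channel map,
    so a stream round-trips through plain text with zero extra files.
    """
    cols = {"macrotime_ticks": stream.macrotimes, "detector_id": stream.detectors}
    if stream.microtimes is not None:
        cols["microtime_bin"] = stream.microtimes
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# clock_rate_hz={stream.clock_rate!r}\n")
        if stream.microtimes is not None:
            fh.write(f"# microtime_resolution_ps={stream.microtime_resolution_ps!r}\n")
            fh.write(f"# microtime_range={stream.microtime_range}\n")
        for det in sorted(stream.channel_map.channels):
            band, pol = stream.channel_map.channels[det]
            fh.write(f"# channel={det}:{band}:{pol}\n")
        df.to_csv(fh, index=False)


def read_photon_csv(path) -> PhotonStream:
    header: dict[str, str] = {}
    channels: dict[int, tuple[str, str]] = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            key, _, val = line[1:].strip().partition("=")
            key = key.strip()
            if key == "channel":
                det, band, pol = val.split(":")
                channels[int(det)] = (band, pol)
            else:
                header[key] = val
    if "clock_rate_hz" not in header:
        raise FormatError("missing mandatory header field 'clock_rate_hz'")
    df = pd.read_csv(path, comment="#")
    for col in ("macrotime_ticks", "detector_id"):
        if col not in df:
            raise FormatError(f"missing mandatory column '{col}'")
    return PhotonStream(
        macrotimes=df["macrotime_ticks"].to_numpy(np.int64),
        clock_rate=float(header["clock_rate_hz"]),
        detectors=df["detector_id"].to_numpy(np.int16),
        channel_map=ChannelMap(channels) if channels else ChannelMap.simple(),
        microtimes=df["microtime_bin"].to_numpy() if "microtime_bin" in df else None,
        microtime_resolution_ps=float(header.get("microtime_resolution_ps", 0) or 0) or None,
        microtime_range=int(header["microtime_range"]) if "microtime_range" in header else None,
    )
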