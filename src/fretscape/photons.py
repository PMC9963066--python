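"""Photon-record streams: the atomic observable of a confocal smFRET experiment.

A stream is a time-ordered sequence of detected photons, each carrying the
detection channel (donor or acceptor), the excitation pulse it followed
(donor or acceptor pulse, for pulsed interleaved excitation), and optionally
the micro-time delay since the excitation pulse (ns) for lifetime work.

Two on-disk dialects are supported:

* a CSV table with columns ``time_s``, ``channel`` (``donor``/``acceptor``),
  ``excitation`` (``donor_pulse``/``acceptor_pulse``) and optional
  ``delay_ns``;
* a photon-HDF5-style container with datasets ``photon_data/timestamps`` (s),
  ``photon_data/detectors`` (0 donor / 1 acceptor), ``photon_data/excitation``
  (0 donor pulse / 1 acceptor pulse) and optional ``photon_data/nanotimes``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["DONOR", "ACCEPTOR", "DONOR_PULSE", "ACCEPTOR_PULSE", "PhotonStream"]

DONOR = 0
ACCEPTOR = 1
DONOR_PULSE = 0
ACCEPTOR_PULSE = 1

_CHANNEL_NAMES = {DONOR: "donor", ACCEPTOR: "acceptor"}
_EXCITATION_NAMES = {DONOR_PULSE: "donor_pulse", ACCEPTOR_PULSE: "acceptor_pulse"}
_CHANNEL_CODES = {v: k for k, v in _CHANNEL_NAMES.items()}
_EXCITATION_CODES = {v: k for k, v in _EXCITATION_NAMES.items()}


@dataclass
class PhotonStream:
    """Time-sorted photon records.

    Attributes
    ----------
    times : ndarray of float
        Macro-time arrival times in seconds, monotone non-decreasing.
    channels : ndarray of uint8
        Detection channel per photon (0 donor, 1 acceptor).
    excitations : ndarray of uint8
        Excitation pulse label per photon (0 donor pulse, 1 acceptor pulse).
    delays_ns : ndarray of float, optional
        Micro-time since the excitation pulse, in ns.
    """

    times: np.ndarray
    channels: np.ndarray
    excitations: np.ndarray
    delays_ns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.channels = np.asarray(self.channels, dtype=np.uint8)
        self.excitations = np.asarray(self.excitations, dtype=np.uint8)
        if self.delays_ns is not None:
            self.delays_ns = np.asarray(self.delays_ns, dtype=float)
        n = len(self.times)
        if len(self.channels) != n or len(self.excitations) != n:
            raise ValueError("times, channels and excitations must have equal length")
        if self.delays_ns is not None and len(self.delays_ns) != n:
            raise ValueError("delays_ns length must match times")
        if n and self.times[0] < 0:
            raise ValueError("photon times must be non-negative")
        if n and np.any(np.diff(self.times) < 0):
            raise ValueError("photon stream is not time-sorted")
        if self.delays_ns is not None and n and np.any(self.delays_ns < 0):
            raise ValueError("photon delays must be non-negative")
        if n and not np.all(np.isin(self.channels, (DONOR, ACCEPTOR))):
            raise ValueError("channels must be 0 (donor) or 1 (acceptor)")
        if n and not np.all(np.isin(self.excitations, (DONOR_PULSE, ACCEPTOR_PULSE))):
            raise ValueError("excitations must be 0 (donor pulse) or 1 (acceptor pulse)")

    def __len__(self) -> int:
        return len(self.times)

    def select(self, mask: np.ndarray) -> "PhotonStream":
        """Subset of the stream given a boolean mask (order preserved)."""
        return PhotonStream(
            self.times[mask],
            self.channels[mask],
            self.excitations[mask],
            None if self.delays_ns is None else self.delays_ns[mask],
        )

    @classmethod
    def concatenate(cls, streams: list["PhotonStream"]) -> "PhotonStream":
        """Concatenate already time-ordered, non-overlapping streams."""
        if not streams:
            return cls(np.empty(0), np.empty(0, np.uint8), np.empty(0, np.uint8))
        delays = None
        if all(s.delays_ns is not None for s in streams):
            delays = np.concatenate([s.delays_ns for s in streams])
        return cls(
            np.concatenate([s.times for s in streams]),
            np.concatenate([s.channels for s in streams]),
            np.concatenate([s.excitations for s in streams]),
            delays,
        )

    # ------------------------------------------------------------------ I/O

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_s": self.times,
                "channel": [_CHANNEL_NAMES[c] for c in self.channels],
                "excitation": [_EXCITATION_NAMES[e] for e in self.excitations],
            }
        )
        if self.delays_ns is not None:
            df["delay_ns"] = self.delays_ns
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PhotonStream":
        channels = df["channel"].map(_CHANNEL_CODES)
        excitations = df["excitation"].map(_EXCITATION_CODES)
        if channels.isna().any():
            raise ValueError("unknown channel label in table")
        if excitations.isna().any():
            raise ValueError("unknown excitation label in table")
        delays = df["delay_ns"].to_numpy() if "delay_ns" in df.columns else None
        return cls(df["time_s"].to_numpy(), channels.to_numpy(), excitations.to_numpy(), delays)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhotonStream":
        return cls.from_dataframe(pd.read_csv(path))

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            g = f.create_group("photon_data")
            g.create_dataset("timestamps", data=self.times)
            g.create_dataset("detectors", data=self.channels)
            g.create_dataset("excitation", data=self.excitations)
            if self.delays_ns is not None:
                g.create_dataset("nanotimes", data=self.delays_ns)
            g.attrs["timestamps_unit"] = "s"
            g.attrs["nanotimes_unit"] = "ns"

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "PhotonStream":
        with h5py.File(path, "r") as f:
            g = f["photon_data"]
            delays = g["nanotimes"][:] if "nanotimes" in g else None
            return cls(g["timestamps"][:], g["detectors"][:], g["excitation"][:], delays)
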