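"""Burst analysis: photon streams → bursts → corrected efficiencies and histograms.

A burst is a contiguous cluster of photons emitted while a single molecule
transits the confocal volume.  Bursts are found with an all-photon
interphoton-gap criterion: photons separated by more than ``max_gap`` never
share a burst, and a cluster is kept when it holds at least ``threshold``
donor-excitation photons.

Per burst, three counts drive the analysis (pulsed interleaved excitation):

* ``n_donor``    — donor-excitation photons detected in the donor channel,
* ``n_acceptor`` — donor-excitation photons detected in the acceptor channel,
* ``n_aa``       — acceptor-excitation photons detected in the acceptor
  channel (reports on acceptor presence).

The corrected transfer efficiency is E = nA'/(nA' + γ·nD') with background,
crosstalk and direct-excitation subtraction applied to the raw counts, and
the labelling stoichiometry S = (nD+nA)/(nD+nA+nAA) separates 1:1-labelled
molecules (S ≈ 0.5) from donor-only (S ≈ 1) and acceptor-only (S ≈ 0)
species; histograms retain bursts inside an S window (default 0.3–0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .instrument import FretSetup
from .photons import ACCEPTOR, ACCEPTOR_PULSE, DONOR, DONOR_PULSE, PhotonStream

__all__ = [
    "Burst",
    "EfficiencyHistogram",
    "detect_bursts",
    "burst_efficiency",
    "burst_stoichiometry",
    "build_histogram",
    "burst_variance_analysis",
    "BurstVarianceResult",
]

#: Default reporting range for corrected efficiencies; the sub-zero and
#: above-one margins absorb background over-subtraction.
E_RANGE = (-0.1, 1.1)

DEFAULT_THRESHOLD = 50
DEFAULT_MAX_GAP_S = 100e-6
DEFAULT_S_WINDOW = (0.3, 0.7)
DEFAULT_BINS = 50


@dataclass
class Burst:
    """A contiguous photon cluster with per-channel counts.

    ``dex_channels`` keeps the detection-channel sequence of the burst's
    donor-excitation photons (0 donor / 1 acceptor, in arrival order) so that
    windowed analyses such as burst variance analysis can re-slice the burst.
    """

    start: float
    stop: float
    n_donor: int
    n_acceptor: int
    n_aa: int
    mean_delay_ns: float | None = None
    dex_channels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("burst stop must exceed start")
        if min(self.n_donor, self.n_acceptor, self.n_aa) < 0:
            raise ValueError("photon counts must be non-negative")

    @property
    def size(self) -> int:
        """Donor-excitation photon count (nD + nA)."""
        return self.n_donor + self.n_acceptor

    @property
    def duration(self) -> float:
        return self.stop - self.start


def detect_bursts(
    stream: PhotonStream,
    threshold: int = DEFAULT_THRESHOLD,
    max_gap: float = DEFAULT_MAX_GAP_S,
) -> list[Burst]:
    """Find photon bursts by the all-photon interphoton-gap criterion.

    Parameters
    ----------
    stream : PhotonStream
        Time-sorted photon records (sortedness is validated).
    threshold : int
        Minimum number of donor-excitation photons for a cluster to count as
        a burst.
    max_gap : float
        Maximum interphoton gap (s) within a burst; a larger gap splits
        clusters.

    Returns
    -------
    list of Burst
        Disjoint bursts in time order.  An empty stream yields an empty list.
    """
    times = np.asarray(stream.times, dtype=float)
    if len(times) == 0:
        return []
    if np.any(np.diff(times) < 0):
        raise ValueError("photon stream is not time-sorted")
    if threshold < 1:
        raise ValueError("burst-size threshold must be at least 1")
    if max_gap <= 0:
        raise ValueError("max interphoton gap must be positive")

    breaks = np.flatnonzero(np.diff(times) > max_gap) + 1
    starts = np.concatenate(([0], breaks))
    stops = np.concatenate((breaks, [len(times)]))

    bursts: list[Burst] = []
    for lo, hi in zip(starts, stops):
        ch = stream.channels[lo:hi]
        ex = stream.excitations[lo:hi]
        dex = ex == DONOR_PULSE
        n_d = int(np.sum(dex & (ch == DONOR)))
        n_a = int(np.sum(dex & (ch == ACCEPTOR)))
        if n_d + n_a < threshold:
            continue
        n_aa = int(np.sum((ex == ACCEPTOR_PULSE) & (ch == ACCEPTOR)))
        mean_delay = None
        if stream.delays_ns is not None:
            d = stream.delays_ns[lo:hi][dex & (ch == DONOR)]
            mean_delay = float(np.mean(d)) if len(d) else None
        stop = times[hi - 1]
        if stop <= times[lo]:  # single-instant cluster; give it zero-width epsilon
            stop = times[lo] + 1e-12
        bursts.append(
            Burst(
                start=float(times[lo]),
                stop=float(stop),
                n_donor=n_d,
                n_acceptor=n_a,
                n_aa=n_aa,
                mean_delay_ns=mean_delay,
                dex_channels=ch[dex].copy(),
            )
        )
    return bursts


def _corrected_counts(burst: Burst, setup: FretSetup) -> tuple[float, float]:
    dur = burst.duration
    n_d = burst.n_donor - setup.bg_donor_hz * dur
    n_a = (
        burst.n_acceptor
        - setup.bg_acceptor_hz * dur
        - setup.crosstalk * n_d
        - setup.direct_excitation * burst.n_aa
    )
    return n_d, n_a


def burst_efficiency(burst: Burst, setup: FretSetup) -> float:
    """Corrected transfer efficiency of a burst, clipped to the reporting range.

    E = nA' / (nA' + γ nD') after background, crosstalk and direct-excitation
    subtraction.  With neutral corrections this is exactly nA/(nA+nD).
    Returns NaN when heavy background subtraction wipes out the total signal
    (caller should drop such bursts).
    """
    if burst.size == 0:
        raise ValueError("burst has no donor-excitation photons; rejected")
    n_d, n_a = _corrected_counts(burst, setup)
    denom = n_a + setup.gamma * n_d
    if denom <= 0:
        return float("nan")
    return float(np.clip(n_a / denom, *E_RANGE))


def burst_stoichiometry(burst: Burst, setup: FretSetup | None = None) -> float:
    """Labelling stoichiometry S = (nD + nA) / (nD + nA + nAA) ∈ [0, 1]."""
    total = burst.size + burst.n_aa
    if total == 0:
        raise ValueError("burst has no photons; rejected")
    return burst.size / total


@dataclass
class EfficiencyHistogram:
    """Binned burst transfer efficiencies.

    ``counts`` sums to ``n_bursts``; ``bin_edges`` are strictly increasing.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_bursts: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if int(np.sum(self.counts)) != self.n_bursts:
            raise ValueError("histogram counts must sum to n_bursts")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def is_empty(self) -> bool:
        return self.n_bursts == 0

    def normalized(self) -> np.ndarray:
        """Counts as a probability mass per bin (zeros if empty)."""
        if self.n_bursts == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.n_bursts

    @classmethod
    def from_efficiencies(
        cls, efficiencies: np.ndarray, bins: int = DEFAULT_BINS, e_range=E_RANGE
    ) -> "EfficiencyHistogram":
        e = np.asarray(efficiencies, dtype=float)
        e = e[np.isfinite(e)]
        counts, edges = np.histogram(e, bins=bins, range=e_range)
        return cls(bin_edges=edges, counts=counts, n_bursts=int(counts.sum()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "e_lo": self.bin_edges[:-1],
                "e_hi": self.bin_edges[1:],
                "count": self.counts,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EfficiencyHistogram":
        df = pd.read_csv(path)
        edges = np.append(df["e_lo"].to_numpy(), df["e_hi"].iloc[-1])
        counts = df["count"].to_numpy()
        return cls(bin_edges=edges, counts=counts, n_bursts=int(counts.sum()))


def build_histogram(
    bursts: list[Burst],
    setup: FretSetup,
    s_window: tuple[float, float] = DEFAULT_S_WINDOW,
    bins: int = DEFAULT_BINS,
    e_range=E_RANGE,
) -> EfficiencyHistogram:
    """Histogram of corrected efficiencies for stoichiometry-selected bursts.

    Only bursts whose stoichiometry falls inside ``s_window`` (inclusive) are
    counted, which removes donor-only (S ≈ 1) and acceptor-only (S ≈ 0)
    molecules.  An empty retained set yields a valid all-zero histogram.
    """
    s_lo, s_hi = s_window
    es = []
    for b in bursts:
        if b.size == 0:
            continue
        s = burst_stoichiometry(b)
        if not s_lo <= s <= s_hi:
            continue
        e = burst_efficiency(b, setup)
        if np.isfinite(e):
            es.append(e)
    return EfficiencyHistogram.from_efficiencies(np.asarray(es), bins=bins, e_range=e_range)


# -------------------------------------------------------- burst variance analysis


@dataclass
class BurstVarianceResult:
    """Windowed per-burst efficiency spread vs the shot-noise expectation.

    ``table`` has one row per analysed burst with columns ``e_mean`` (mean of
    window efficiencies), ``sd_e`` (standard deviation over windows),
    ``expected_sd`` (binomial shot-noise sqrt(E(1-E)/window)) and
    ``n_windows``.  Bursts too short for two windows are skipped and counted
    in ``n_skipped``.
    """

    table: pd.DataFrame
    window_photons: int
    n_skipped: int

    def fraction_within_envelope(self, alpha: float = 0.975) -> float:
        """Fraction of bursts whose window variance is inside the shot-noise
        envelope at confidence ``alpha``.

        Under a static state, (n_w - 1)·sd²/σ_shot² is approximately
        chi-squared with n_w - 1 degrees of freedom; a burst falls inside the
        envelope when its sd does not exceed the alpha-quantile bound.
        """
        t = self.table
        if len(t) == 0:
            return float("nan")
        dof = t["n_windows"] - 1
        bound = t["expected_sd"] * np.sqrt(chi2.ppf(alpha, dof) / dof)
        return float(np.mean(t["sd_e"] <= bound))


def burst_variance_analysis(
    bursts: list[Burst], window_photons: int = 5
) -> BurstVarianceResult:
    """Burst variance analysis: detect within-burst dynamics beyond shot noise.

    Each burst's donor-excitation photon sequence is cut into consecutive
    windows of ``window_photons`` photons; the standard deviation of the
    per-window efficiencies is compared with the binomial expectation
    sqrt(Ē(1-Ē)/window_photons).  Static states scatter inside that envelope;
    conformational exchange on the burst timescale inflates the spread.
    """
    if window_photons < 2:
        raise ValueError("window must hold at least 2 photons")
    rows = []
    n_skipped = 0
    for i, b in enumerate(bursts):
        seq = b.dex_channels
        if seq is None:
            raise ValueError("bursts must carry their photon-channel sequence")
        n_windows = len(seq) // window_photons
        if n_windows < 2:
            n_skipped += 1
            continue
        trimmed = seq[: n_windows * window_photons].reshape(n_windows, window_photons)
        e_w = trimmed.mean(axis=1)
        e_mean = float(e_w.mean())
        sd = float(e_w.std(ddof=1))
        expected = float(np.sqrt(max(e_mean * (1 - e_mean), 0.0) / window_photons))
        rows.append(
            {
                "burst": i,
                "e_mean": e_mean,
                "sd_e": sd,
                "expected_sd": expected,
                "n_windows": n_windows,
            }
        )
    table = pd.DataFrame(rows, columns=["burst", "e_mean", "sd_e", "expected_sd", "n_windows"])
    return BurstVarianceResult(table=table, window_photons=window_photons, n_skipped=n_skipped)
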