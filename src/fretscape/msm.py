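"""Kinetic Monte Carlo photon simulation from a Markov state model.

A :class:`MarkovModel` holds a row-stochastic transition matrix T at lag
time τ_lag (ns), per-state inter-dye distances (or fixed efficiencies), and
a dimensionless time-rescaling factor that maps the model's intrinsic
timescale onto the experimental photon timescale: the state path advances by
one T-step every τ_lag × rescale of wall-clock time.  The default rescale of
225 stretches nanosecond-lag conformational kinetics into the microsecond-
to-millisecond window probed by photon bursts.

The simulator turns the state path into photon records: photon arrivals are
a Poisson process at the burst count rate, and each donor-excitation photon
is detected in the acceptor channel with the current state's transfer
efficiency — which reproduces both shot noise (binomial counting) and
kinetic averaging (states mixing within a burst).  Crosstalk, direct
excitation and background are applied at detection; the gamma imbalance is
an analysis-side correction and is not simulated.  Simulated streams feed
the same burst pipeline as experimental data, so predicted histograms are
directly comparable to measured ones.

Also provided: a minimal maximum-likelihood-style MSM estimator for discrete
state trajectories (symmetrized transition counts at a lag, hence detailed
balance by construction) and a normalized-L1 histogram distance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .bursts import (
    DEFAULT_BINS,
    DEFAULT_MAX_GAP_S,
    DEFAULT_THRESHOLD,
    EfficiencyHistogram,
    build_histogram,
    detect_bursts,
)
from .instrument import FretSetup
from .photons import (
    ACCEPTOR,
    ACCEPTOR_PULSE,
    DONOR,
    DONOR_PULSE,
    PhotonStream,
)
from .polymer import forster_efficiency

__all__ = [
    "MarkovModel",
    "SimConfig",
    "simulate_photons",
    "predict_histogram",
    "estimate_msm",
    "compare_histograms",
]

DEFAULT_RESCALE = 225.0


@dataclass
class MarkovModel:
    """Discrete-state kinetic model driving the photon simulator.

    Parameters
    ----------
    transition_matrix : (n, n) array
        Row-stochastic transition probabilities at the lag time.
    lag_ns : float
        Lag time of the transition matrix, in ns.
    distances_nm : (n,) array, optional
        Per-state inter-dye distance; converted to efficiencies through the
        Förster relation of the setup in use.
    efficiencies : (n,) array, optional
        Per-state fixed transfer efficiency (bypasses distances).
    rescale : float
        Time-rescaling factor: the state path advances by one matrix step
        every ``lag_ns * rescale`` nanoseconds of experiment time.
    populations : (n,) array, optional
        Stationary distribution; computed from the matrix when omitted.
    """

    transition_matrix: np.ndarray
    lag_ns: float
    distances_nm: np.ndarray | None = None
    efficiencies: np.ndarray | None = None
    rescale: float = DEFAULT_RESCALE
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.transition_matrix, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix must be row-stochastic")
        self.transition_matrix = t
        if self.lag_ns <= 0:
            raise ValueError("lag time must be positive")
        if self.rescale <= 0:
            raise ValueError("rescale factor must be positive")
        if self.distances_nm is None and self.efficiencies is None:
            raise ValueError("provide per-state distances or efficiencies")
        if self.distances_nm is not None:
            self.distances_nm = np.asarray(self.distances_nm, dtype=float)
            if len(self.distances_nm) != self.n_states:
                raise ValueError("need one distance per state")
        if self.efficiencies is not None:
            self.efficiencies = np.asarray(self.efficiencies, dtype=float)
            if len(self.efficiencies) != self.n_states:
                raise ValueError("need one efficiency per state")
        if self.populations is None:
            self.populations = self.stationary_distribution()
        else:
            self.populations = np.asarray(self.populations, dtype=float)
            pi = self.populations
            if not np.allclose(pi @ t, pi, atol=1e-6):
                raise ValueError("populations is not a left fixed point of the matrix")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def dwell_step_s(self) -> float:
        """Experiment-time duration of one matrix step (s)."""
        return self.lag_ns * 1e-9 * self.rescale

    def stationary_distribution(self) -> np.ndarray:
        """Stationary vector by power iteration on the transpose."""
        t = self.transition_matrix
        pi = np.full(self.n_states, 1.0 / self.n_states)
        for _ in range(100000):
            new = pi @ t
            if np.abs(new - pi).max() < 1e-13:
                pi = new
                break
            pi = new
        return pi / pi.sum()

    def state_efficiencies(self, setup: FretSetup) -> np.ndarray:
        if self.efficiencies is not None:
            return self.efficiencies
        return forster_efficiency(self.distances_nm, setup.r0_nm)

    def sample_path(self, n_steps: int, rng: np.random.Generator, start: int | None = None) -> np.ndarray:
        """Sample a state path of ``n_steps`` steps (stationary start by default)."""
        cum = np.cumsum(self.transition_matrix, axis=1)
        path = np.empty(n_steps, dtype=np.int64)
        s = (
            int(rng.choice(self.n_states, p=self.populations))
            if start is None
            else int(start)
        )
        u = rng.random(n_steps)
        for i in range(n_steps):
            path[i] = s
            s = int(np.searchsorted(cum[s], u[i]))
        return path

    def is_reversible(self, atol: float = 1e-8) -> bool:
        pi = self.populations
        flux = pi[:, None] * self.transition_matrix
        return bool(np.allclose(flux, flux.T, atol=atol))

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        d = {
            "transition_matrix": self.transition_matrix.tolist(),
            "lag_ns": self.lag_ns,
            "rescale": self.rescale,
            "populations": self.populations.tolist(),
        }
        if self.distances_nm is not None:
            d["distances_nm"] = self.distances_nm.tolist()
        if self.efficiencies is not None:
            d["efficiencies"] = self.efficiencies.tolist()
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "MarkovModel":
        return cls(
            transition_matrix=np.asarray(d["transition_matrix"]),
            lag_ns=d["lag_ns"],
            distances_nm=np.asarray(d["distances_nm"]) if "distances_nm" in d else None,
            efficiencies=np.asarray(d["efficiencies"]) if "efficiencies" in d else None,
            rescale=d.get("rescale", DEFAULT_RESCALE),
            populations=np.asarray(d["populations"]) if "populations" in d else None,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkovModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class SimConfig:
    """Photon-simulation settings.

    ``photon_rate_hz`` is the donor-excitation detection rate during a
    burst; an equal acceptor-excitation rate is interleaved so that
    double-labelled molecules sit at stoichiometry ≈ 0.5.  Bursts have fixed
    duration and are spaced far apart so the burst search recovers them.
    """

    photon_rate_hz: float = 1.0e5
    burst_duration_s: float = 1.0e-3
    n_bursts: int = 1000
    burst_spacing_s: float = 1.0e-2
    aex_rate_hz: float | None = None  # defaults to photon_rate_hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_rate_hz < 0:
            raise ValueError("photon rate must be non-negative")
        if self.burst_duration_s <= 0:
            raise ValueError("burst duration must be positive")
        if self.n_bursts < 1:
            raise ValueError("need at least one burst")
        if self.burst_spacing_s <= self.burst_duration_s:
            raise ValueError("burst spacing must exceed the burst duration")


def _burst_rng(seed: int, burst_index: int) -> np.random.Generator:
    """Independent substream per burst; stable under changes of n_bursts."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(burst_index,)))


def simulate_photons(
    msm: MarkovModel, setup: FretSetup, cfg: SimConfig
) -> tuple[PhotonStream, pd.DataFrame]:
    """Kinetic Monte Carlo photon trajectories from a Markov state model.

    Returns the photon stream together with a ground-truth table (one row
    per burst: start time, dominant state, per-state occupancy fractions and
    the time-averaged efficiency along the state path).
    """
    e_states = msm.state_efficiencies(setup)
    if np.any((e_states < 0) | (e_states > 1)):
        raise ValueError("state efficiencies must lie in [0, 1]")
    dt = msm.dwell_step_s
    aex_rate = cfg.aex_rate_hz if cfg.aex_rate_hz is not None else cfg.photon_rate_hz

    streams: list[PhotonStream] = []
    truth_rows = []
    for b in range(cfg.n_bursts):
        rng = _burst_rng(cfg.seed, b)
        t0 = b * cfg.burst_spacing_s
        n_steps = int(np.ceil(cfg.burst_duration_s / dt)) + 1
        path = msm.sample_path(n_steps, rng)

        n_dex = rng.poisson(cfg.photon_rate_hz * cfg.burst_duration_s)
        t_dex = np.sort(rng.random(n_dex)) * cfg.burst_duration_s
        state_at = path[np.minimum((t_dex / dt).astype(np.int64), n_steps - 1)]
        p_acc = e_states[state_at]
        is_acc = rng.random(n_dex) < p_acc
        # spectral crosstalk: donor emission detected in the acceptor channel
        if setup.crosstalk > 0:
            leak = (~is_acc) & (rng.random(n_dex) < setup.crosstalk)
            is_acc = is_acc | leak
        ch_dex = np.where(is_acc, ACCEPTOR, DONOR).astype(np.uint8)

        n_aex = rng.poisson(aex_rate * cfg.burst_duration_s)
        t_aex = np.sort(rng.random(n_aex)) * cfg.burst_duration_s

        # background photons across the burst window in both channels
        n_bg_d = rng.poisson(setup.bg_donor_hz * cfg.burst_duration_s)
        n_bg_a = rng.poisson(setup.bg_acceptor_hz * cfg.burst_duration_s)
        t_bg = np.sort(rng.random(n_bg_d + n_bg_a)) * cfg.burst_duration_s
        ch_bg = np.concatenate(
            [np.full(n_bg_d, DONOR, np.uint8), np.full(n_bg_a, ACCEPTOR, np.uint8)]
        )
        rng.shuffle(ch_bg)

        times = np.concatenate([t_dex, t_aex, t_bg]) + t0
        chans = np.concatenate([ch_dex, np.full(n_aex, ACCEPTOR, np.uint8), ch_bg])
        excs = np.concatenate(
            [
                np.full(n_dex, DONOR_PULSE, np.uint8),
                np.full(n_aex, ACCEPTOR_PULSE, np.uint8),
                np.full(n_bg_d + n_bg_a, DONOR_PULSE, np.uint8),
            ]
        )
        order = np.argsort(times, kind="stable")
        streams.append(PhotonStream(times[order], chans[order], excs[order]))

        occupancy = np.bincount(path, minlength=msm.n_states) / n_steps
        truth_rows.append(
            {
                "burst": b,
                "start_s": t0,
                "dominant_state": int(np.argmax(occupancy)),
                "path_mean_e": float(e_states[path].mean()),
                **{f"occ_{s}": occupancy[s] for s in range(msm.n_states)},
            }
        )

    stream = PhotonStream.concatenate(streams)
    return stream, pd.DataFrame(truth_rows)


def predict_histogram(
    msm: MarkovModel,
    setup: FretSetup,
    cfg: SimConfig,
    bins: int = DEFAULT_BINS,
    threshold: int = DEFAULT_THRESHOLD,
    max_gap: float = DEFAULT_MAX_GAP_S,
    s_window=(0.3, 0.7),
) -> tuple[EfficiencyHistogram, pd.DataFrame]:
    """Simulated transfer-efficiency histogram for a Markov state model.

    Runs the kinetic Monte Carlo simulator, the burst search and the
    stoichiometry-filtered histogram in sequence; returns the histogram and
    the per-burst ground-truth provenance table.
    """
    stream, truth = simulate_photons(msm, setup, cfg)
    bursts = detect_bursts(stream, threshold=threshold, max_gap=max_gap)
    hist = build_histogram(bursts, setup, s_window=s_window, bins=bins)
    return hist, truth


def estimate_msm(
    trajectories: list[np.ndarray], lag_steps: int = 1, lag_ns: float | None = None
) -> MarkovModel:
    """Estimate a Markov state model from discrete state trajectories.

    Transition counts at ``lag_steps`` are symmetrized, (C + Cᵀ)/2, then
    row-normalized — which enforces detailed balance with respect to the
    resulting stationary vector.  States never visited are dropped with a
    warning; a reducible count graph (disconnected blocks) also warns.

    The returned model has per-state fixed efficiencies of NaN placeholders
    replaced by a uniform 0.5 — callers attach real distances or
    efficiencies before simulating.
    """
    trajs = [np.asarray(t, dtype=np.int64) for t in trajectories if len(t) > 0]
    if not trajs:
        raise ValueError("need at least one non-empty trajectory")
    if lag_steps < 1:
        raise ValueError("lag must be at least 1 step")
    n = int(max(t.max() for t in trajs)) + 1
    counts = np.zeros((n, n))
    for t in trajs:
        if len(t) > lag_steps:
            np.add.at(counts, (t[:-lag_steps], t[lag_steps:]), 1.0)
    visited = counts.sum(axis=0) + counts.sum(axis=1) > 0
    if not visited.all():
        dropped = np.flatnonzero(~visited)
        warnings.warn(f"states never visited dropped from the model: {dropped.tolist()}")
        counts = counts[np.ix_(visited, visited)]
    sym = 0.5 * (counts + counts.T)
    if np.any(sym.sum(axis=1) == 0):
        raise ValueError("a visited state has no transitions at this lag")
    n_comp, _ = connected_components((sym > 0).astype(int), directed=False)
    if n_comp > 1:
        warnings.warn(
            f"transition graph is reducible ({n_comp} disconnected blocks); "
            "stationary distribution is not unique"
        )
    t_mat = sym / sym.sum(axis=1, keepdims=True)
    return MarkovModel(
        transition_matrix=t_mat,
        lag_ns=lag_ns if lag_ns is not None else float(lag_steps),
        efficiencies=np.full(t_mat.shape[0], 0.5),
        rescale=DEFAULT_RESCALE,
    )


def compare_histograms(a: EfficiencyHistogram, b: EfficiencyHistogram) -> float:
    """Per-bin L1 distance between normalized histograms.

    Symmetric, zero iff the normalized histograms are identical, and at most
    2 (disjoint supports).  Requires identical binning.
    """
    if len(a.bin_edges) != len(b.bin_edges) or not np.allclose(a.bin_edges, b.bin_edges):
        raise ValueError("histograms must share identical binning")
    return float(np.abs(a.normalized() - b.normalized()).sum())
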