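"""Generators emulating every input the raw study data would provide.

Real inputs to this kind of analysis are photon streams from a confocal
microscope, per-condition population fractions, Markov state models built
from MD trajectories, and coordinate ensembles.  None of these are needed to
exercise the pipeline: each generator here produces the corresponding input
with a planted, machine-readable ground truth and a mandatory seed, and
writes in the same formats the analysis reads (CSV / photon-HDF5-style /
multi-model PDB), so the generators double as format round-trip tests.

Every generator is deterministic: the same (spec, seed) yields byte-identical
output.  Burst sizes follow a log-normal distribution (median 80
donor-excitation photons) — a realistic spread for diffusing molecules —
and per-population burst counts are binomial at the population's
distribution-averaged efficiency, which is the static-population behaviour;
attaching a Markov model to a population routes it through the kinetic
Monte Carlo simulator instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ConformerEnsemble
from .instrument import FretSetup
from .msm import MarkovModel, SimConfig, simulate_photons
from .photons import (
    ACCEPTOR,
    ACCEPTOR_PULSE,
    DONOR,
    DONOR_PULSE,
    PhotonStream,
)
from .polymer import DistanceModel, mean_efficiency
from .thermo import ThermoModel, TitrationSeries, _series_from_matrix

__all__ = [
    "Population",
    "ScenarioSpec",
    "make_burst_dataset",
    "make_titration_dataset",
    "make_toy_ensemble",
    "make_msm",
]

DEFAULT_BURST_SIZE_MEDIAN = 80.0
DEFAULT_BURST_SIZE_SIGMA = 0.4  # log-normal shape parameter
MIN_BURST_SIZE = 15
BURST_RATE_HZ = 1.0e5
BURST_SPACING_S = 1.0e-2


@dataclass(frozen=True)
class Population:
    """One conformational state of a burst scenario.

    ``model`` is a distance model (or use ``fixed_efficiency``); ``weight``
    is the population fraction; an optional ``msm`` makes the population
    dynamic (bursts come from the kinetic Monte Carlo simulator).
    """

    name: str
    model: DistanceModel
    weight: float
    msm: MarkovModel | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("population weight must be non-negative")


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for a synthetic burst dataset.

    Weights are normalized internally; the seed is mandatory for
    reproducibility.
    """

    populations: tuple[Population, ...]
    setup: FretSetup = field(default_factory=FretSetup)
    n_bursts: int = 2000
    burst_size_median: float = DEFAULT_BURST_SIZE_MEDIAN
    burst_size_sigma: float = DEFAULT_BURST_SIZE_SIGMA
    donor_only_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.populations) == 0:
            raise ValueError("scenario needs at least one population")
        total = sum(p.weight for p in self.populations)
        if total <= 0:
            raise ValueError("population weights must sum to a positive value")
        if not 0 <= self.donor_only_fraction < 1:
            raise ValueError("donor-only fraction must lie in [0, 1)")
        if self.n_bursts < 1:
            raise ValueError("need at least one burst")

    @property
    def weights(self) -> np.ndarray:
        w = np.array([p.weight for p in self.populations], dtype=float)
        return w / w.sum()


def _burst_stream(
    rng: np.random.Generator,
    t0: float,
    n_dex: int,
    e_true: float,
    n_aex: int,
) -> PhotonStream:
    """One burst's photons: binomial donor/acceptor counts plus PIE photons."""
    duration = n_dex / BURST_RATE_HZ
    t_dex = np.sort(rng.random(n_dex)) * duration
    ch_dex = np.where(rng.random(n_dex) < e_true, ACCEPTOR, DONOR).astype(np.uint8)
    t_aex = np.sort(rng.random(n_aex)) * duration
    times = np.concatenate([t_dex, t_aex]) + t0
    chans = np.concatenate([ch_dex, np.full(n_aex, ACCEPTOR, np.uint8)])
    excs = np.concatenate(
        [np.full(n_dex, DONOR_PULSE, np.uint8), np.full(n_aex, ACCEPTOR_PULSE, np.uint8)]
    )
    order = np.argsort(times, kind="stable")
    return PhotonStream(times[order], chans[order], excs[order])


def make_burst_dataset(spec: ScenarioSpec) -> tuple[PhotonStream, pd.DataFrame]:
    """Synthetic photon stream with per-burst ground-truth labels.

    Bursts are placed far apart (10 ms spacing) so the default burst search
    recovers them.  Double-labelled bursts carry acceptor-excitation photons
    at parity with donor-excitation ones (stoichiometry ≈ 0.5); donor-only
    molecules carry none (stoichiometry 1) and emit only donor photons.

    Returns the stream and a table with one row per burst: population label,
    true mean efficiency, photon counts and the donor-only flag.
    """
    weights = spec.weights
    e_means = []
    for p in spec.populations:
        e, _ = mean_efficiency(p.model, spec.setup.r0_nm)
        e_means.append(e)

    streams: list[PhotonStream] = []
    truth_rows = []
    for b in range(spec.n_bursts):
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(b,)))
        t0 = b * BURST_SPACING_S
        n_dex = max(
            MIN_BURST_SIZE,
            int(round(np.exp(rng.normal(np.log(spec.burst_size_median), spec.burst_size_sigma)))),
        )
        donor_only = rng.random() < spec.donor_only_fraction
        if donor_only:
            label, e_true = "donor_only", 0.0
            stream = _burst_stream(rng, t0, n_dex, 0.0, n_aex=0)
        else:
            idx = int(rng.choice(len(weights), p=weights))
            pop = spec.populations[idx]
            label = pop.name
            if pop.msm is not None:
                cfg = SimConfig(
                    photon_rate_hz=BURST_RATE_HZ,
                    burst_duration_s=n_dex / BURST_RATE_HZ,
                    n_bursts=1,
                    burst_spacing_s=1.0,
                    seed=int(rng.integers(2**31 - 1)),
                )
                stream, sub_truth = simulate_photons(pop.msm, spec.setup, cfg)
                stream = PhotonStream(
                    stream.times + t0, stream.channels, stream.excitations
                )
                e_true = float(sub_truth["path_mean_e"].iloc[0])
            else:
                e_true = e_means[idx]
                n_aex = int(rng.poisson(n_dex))
                stream = _burst_stream(rng, t0, n_dex, e_true, n_aex)
        streams.append(stream)
        truth_rows.append(
            {
                "burst": b,
                "label": label,
                "e_true": e_true,
                "n_photons": len(stream),
                "donor_only": donor_only,
            }
        )
    return PhotonStream.concatenate(streams), pd.DataFrame(truth_rows)


def make_titration_dataset(
    thermo: ThermoModel,
    concentrations: np.ndarray,
    noise_sd: float,
    seed: int,
) -> TitrationSeries:
    """Observed-fraction series from a thermodynamic model plus noise.

    Gaussian noise (sd ``noise_sd``) is added to the exact Boltzmann
    fractions, truncated at [0, 1] and renormalized per condition — note the
    truncation biases fractions near the simplex boundary slightly inward.
    The generating model is attached as ``series.ground_truth``.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    exact = thermo.fractions(conc)
    noisy = np.clip(exact + rng.normal(0.0, noise_sd, size=exact.shape), 0.0, 1.0)
    noisy /= noisy.sum(axis=1, keepdims=True)
    sd = np.full_like(noisy, max(noise_sd, 1e-6))
    series = _series_from_matrix(conc, noisy, sd, thermo.states)
    series.ground_truth = thermo
    return series


def make_msm(
    n_states: int,
    dwell_times_ns: np.ndarray,
    distances_nm: np.ndarray | None = None,
    efficiencies: np.ndarray | None = None,
    lag_ns: float = 10.0,
    rescale: float = 225.0,
    seed: int = 0,
    n_trajectories: int = 4,
    trajectory_length: int = 10000,
) -> tuple[MarkovModel, list[np.ndarray]]:
    """Markov model with exponential-dwell kinetics plus sampled trajectories.

    Self-transition probabilities are exp(-lag/dwell) per state; the escape
    probability is split uniformly over the other states.  Dwell times must
    exceed the lag so the discrete chain resolves the kinetics.
    """
    dwell = np.asarray(dwell_times_ns, dtype=float)
    if len(dwell) != n_states:
        raise ValueError("one dwell time per state required")
    if np.any(dwell <= lag_ns):
        raise ValueError("dwell times must exceed the lag time")
    t = np.zeros((n_states, n_states))
    for i in range(n_states):
        stay = np.exp(-lag_ns / dwell[i])
        t[i, i] = stay
        if n_states > 1:
            t[i, np.arange(n_states) != i] = (1.0 - stay) / (n_states - 1)
        else:
            t[i, i] = 1.0
    if efficiencies is None and distances_nm is None:
        efficiencies = np.linspace(0.9, 0.1, n_states)
    msm = MarkovModel(
        transition_matrix=t,
        lag_ns=lag_ns,
        distances_nm=distances_nm,
        efficiencies=efficiencies,
        rescale=rescale,
    )
    rng = np.random.default_rng(seed)
    trajs = [msm.sample_path(trajectory_length, rng) for _ in range(n_trajectories)]
    return msm, trajs


def make_toy_ensemble(
    n_residues: int,
    n_frames: int,
    planted_contacts: list[tuple[int, int, float]] | None = None,
    subpopulation_geometry: dict | None = None,
    seed: int = 0,
    min_seq_sep: int = 6,
    contact_distance_angstrom: float = 2.5,
    weights: np.ndarray | None = None,
) -> ConformerEnsemble:
    """Residue-level coordinate ensemble with planted contacts and geometry.

    The baseline is a per-frame random flight chain with 3.8 Å steps —
    residue "centres of mass" are generated directly, so the ensemble writes
    cleanly as a pseudo-CA multi-model PDB.

    ``planted_contacts`` is a list of (res_i, res_j, persistence): in that
    fraction of frames (rounded), residue j is placed
    ``contact_distance_angstrom`` from residue i.  Pairs closer in sequence
    than ``min_seq_sep`` are rejected as infeasible.

    ``subpopulation_geometry`` plants box-resolvable structure:
    ``{"labels": {name: weight_fraction}, "pairs": {(a, b): {name: (lo_nm,
    hi_nm)}}}`` — each frame draws a label, then every controlled pair's
    distance is drawn uniformly from that label's range.
    """
    if n_residues < 2 or n_frames < 1:
        raise ValueError("need at least 2 residues and 1 frame")
    rng = np.random.default_rng(seed)
    residue_ids = np.arange(1, n_residues + 1)

    # random flight baseline, 3.8 Å virtual bond
    steps = rng.normal(size=(n_frames, n_residues, 3))
    steps /= np.linalg.norm(steps, axis=2, keepdims=True)
    coords = np.cumsum(3.8 * steps, axis=1)

    labels = None
    if subpopulation_geometry is not None:
        names = list(subpopulation_geometry["labels"])
        probs = np.array([subpopulation_geometry["labels"][n] for n in names], dtype=float)
        probs /= probs.sum()
        labels = rng.choice(names, size=n_frames, p=probs)
        for (a, b), ranges in subpopulation_geometry["pairs"].items():
            ca, cb = a - 1, b - 1
            for f in range(n_frames):
                lo_nm, hi_nm = ranges[str(labels[f])]
                d = rng.uniform(lo_nm, hi_nm) * 10.0  # nm → Å
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                coords[f, cb] = coords[f, ca] + d * direction

    if planted_contacts:
        for res_i, res_j, persistence in planted_contacts:
            if abs(res_j - res_i) < min_seq_sep:
                raise ValueError(
                    f"planted contact ({res_i}, {res_j}) violates the minimum "
                    f"sequence separation {min_seq_sep}"
                )
            if not 0 <= persistence <= 1:
                raise ValueError("contact persistence must lie in [0, 1]")
            k = int(round(persistence * n_frames))
            chosen = rng.choice(n_frames, size=k, replace=False)
            for f in chosen:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                coords[f, res_j - 1] = (
                    coords[f, res_i - 1] + contact_distance_angstrom * direction
                )

    ens = ConformerEnsemble(coords, residue_ids, weights=weights)
    if labels is not None:
        ens.frame_labels = labels
    return ens
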