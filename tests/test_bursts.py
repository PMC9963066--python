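"""Burst search, corrected efficiencies, stoichiometry filtering, histograms, BVA."""

import numpy as np
import pytest

from fretscape import (
    Burst,
    FretSetup,
    PhotonStream,
    build_histogram,
    burst_efficiency,
    burst_stoichiometry,
    burst_variance_analysis,
    detect_bursts,
    make_burst_dataset,
)
from fretscape.polymer import DistanceModel
from fretscape.synthetic import Population, ScenarioSpec


def _cluster(t0: float, n: int, rate: float = 1e5) -> np.ndarray:
    """n regularly spaced photon times starting at t0."""
    return t0 + np.arange(n) / rate


def _stream_from_times(times: np.ndarray) -> PhotonStream:
    n = len(times)
    return PhotonStream(times, np.zeros(n, np.uint8), np.zeros(n, np.uint8))


def _brute_force_clusters(times: np.ndarray, max_gap: float) -> list[np.ndarray]:
    """Independent oracle: linear scan splitting on gaps."""
    clusters, current = [], [times[0]]
    for t_prev, t in zip(times[:-1], times[1:]):
        if t - t_prev > max_gap:
            clusters.append(np.asarray(current))
            current = []
        current.append(t)
    clusters.append(np.asarray(current))
    return clusters


class TestDetectBursts:
    def test_empty_stream(self):
        assert detect_bursts(_stream_from_times(np.empty(0))) == []

    def test_uniform_sparse_stream_has_no_bursts(self):
        # one photon per ms: every gap exceeds the 100 µs limit
        times = np.arange(1000) * 1e-3
        assert detect_bursts(_stream_from_times(times), threshold=50) == []

    def test_two_planted_clusters(self):
        times = np.concatenate([_cluster(0.0, 100), _cluster(1.0, 80)])
        bursts = detect_bursts(_stream_from_times(times), threshold=50, max_gap=1e-4)
        oracle = _brute_force_clusters(times, 1e-4)
        assert len(bursts) == len(oracle) == 2
        assert [b.size for b in bursts] == [len(c) for c in oracle] == [100, 80]

    def test_merging_below_max_gap(self):
        times = np.concatenate([_cluster(0.0, 100), _cluster(0.001 + 5e-5, 100)])
        bursts = detect_bursts(_stream_from_times(times), threshold=50, max_gap=1e-4)
        assert len(bursts) == 1
        assert bursts[0].size == 200

    def test_threshold_counts_donor_excitation_photons(self):
        # 60 donor-excitation + 60 acceptor-excitation photons interleaved:
        # only the 60 donor-excitation photons count toward the threshold
        times = _cluster(0.0, 120)
        exc = np.tile([0, 1], 60).astype(np.uint8)
        stream = PhotonStream(times, np.zeros(120, np.uint8), exc)
        assert detect_bursts(stream, threshold=61) == []
        found = detect_bursts(stream, threshold=60)
        assert len(found) == 1 and found[0].size == 60 and found[0].n_aa == 0

    def test_unsorted_stream_raises(self):
        s = _stream_from_times(_cluster(0.0, 100))
        s.times = s.times[::-1].copy()  # bypass constructor validation
        with pytest.raises(ValueError, match="sorted"):
            detect_bursts(s)

    def test_bursts_are_disjoint_in_time(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 0.1, size=5000))
        bursts = detect_bursts(_stream_from_times(times), threshold=20, max_gap=2e-5)
        for a, b in zip(bursts[:-1], bursts[1:]):
            assert a.stop < b.start


class TestEfficiencyAndStoichiometry:
    def test_symmetric_counts_give_half(self, neutral_setup):
        b = Burst(0, 1e-3, n_donor=50, n_acceptor=50, n_aa=40)
        assert burst_efficiency(b, neutral_setup) == pytest.approx(0.5)

    def test_high_efficiency_burst(self, neutral_setup):
        b = Burst(0, 1e-3, n_donor=2, n_acceptor=98, n_aa=90)
        assert burst_efficiency(b, neutral_setup) == pytest.approx(0.98)

    def test_gamma_correction(self, neutral_setup):
        setup = FretSetup(gamma=2.0)
        b = Burst(0, 1e-3, n_donor=50, n_acceptor=50, n_aa=40)
        assert burst_efficiency(b, setup) == pytest.approx(1.0 / 3.0)

    def test_neutral_equals_raw_ratio_exhaustively(self, neutral_setup):
        # oracle equality over all small counts
        for n_d in range(0, 21):
            for n_a in range(0, 21 - n_d):
                if n_d + n_a == 0:
                    continue
                b = Burst(0, 1e-3, n_donor=n_d, n_acceptor=n_a, n_aa=10)
                assert burst_efficiency(b, neutral_setup) == pytest.approx(
                    n_a / (n_a + n_d), abs=1e-12
                )

    def test_full_correction_formula_hand_check(self):
        setup = FretSetup(
            gamma=1.1, bg_donor_hz=1000, bg_acceptor_hz=500, crosstalk=0.05,
            direct_excitation=0.04,
        )
        b = Burst(0, 1e-3, n_donor=40, n_acceptor=60, n_aa=50)
        n_d = 40 - 1000 * 1e-3
        n_a = 60 - 500 * 1e-3 - 0.05 * n_d - 0.04 * 50
        assert burst_efficiency(b, setup) == pytest.approx(n_a / (n_a + 1.1 * n_d))

    def test_zero_photons_rejected(self, neutral_setup):
        b = Burst(0, 1e-3, n_donor=0, n_acceptor=0, n_aa=10)
        with pytest.raises(ValueError):
            burst_efficiency(b, neutral_setup)
        assert burst_stoichiometry(b) == pytest.approx(0.0)

    def test_stoichiometry_definition(self):
        donor_only = Burst(0, 1e-3, n_donor=80, n_acceptor=0, n_aa=0)
        assert burst_stoichiometry(donor_only) == pytest.approx(1.0)
        balanced = Burst(0, 1e-3, n_donor=25, n_acceptor=25, n_aa=50)
        assert burst_stoichiometry(balanced) == pytest.approx(0.5)

    def test_clipping_to_reporting_range(self):
        setup = FretSetup(bg_acceptor_hz=1e5)  # oversubtracts the acceptor
        b = Burst(0, 1e-3, n_donor=200, n_acceptor=10, n_aa=100)
        assert burst_efficiency(b, setup) == pytest.approx(-0.1)


class TestHistogram:
    def _scenario(self, **kw):
        defaults = dict(
            populations=(
                Population("lo", DistanceModel.fixed_efficiency(0.25), 0.6),
                Population("hi", DistanceModel.fixed_efficiency(0.85), 0.4),
            ),
            n_bursts=800,
            seed=7,
        )
        defaults.update(kw)
        return ScenarioSpec(**defaults)

    def test_count_conservation(self, neutral_setup):
        stream, _ = make_burst_dataset(self._scenario())
        bursts = detect_bursts(stream, threshold=20)
        for window in [(0.3, 0.7), (0.0, 1.0), (0.45, 0.55)]:
            h = build_histogram(bursts, neutral_setup, s_window=window)
            retained = sum(
                1 for b in bursts if window[0] <= burst_stoichiometry(b) <= window[1]
            )
            assert h.counts.sum() == h.n_bursts == retained

    def test_donor_only_removed_by_s_filter(self, neutral_setup):
        stream, truth = make_burst_dataset(
            self._scenario(n_bursts=600, donor_only_fraction=0.3)
        )
        bursts = detect_bursts(stream, threshold=20)
        h = build_histogram(bursts, neutral_setup)
        n_double = (~truth.donor_only).sum()
        assert h.n_bursts <= n_double  # no donor-only sneaks in
        assert h.n_bursts > 0.9 * n_double
        # low-E bin mass stays bimodal around the planted values, no peak at 0
        low_bin = h.counts[h.centers < 0.1].sum()
        assert low_bin / h.n_bursts < 0.02

    def test_single_state_is_unimodal_at_half(self, neutral_setup):
        spec = self._scenario(
            populations=(Population("mid", DistanceModel.fixed_efficiency(0.5), 1.0),),
        )
        stream, _ = make_burst_dataset(spec)
        h = build_histogram(detect_bursts(stream, threshold=20), neutral_setup)
        mean_e = float((h.normalized() * h.centers).sum())
        assert mean_e == pytest.approx(0.5, abs=0.02)

    def test_planted_fractions_recovered_in_bin_mass(self, neutral_setup):
        stream, _ = make_burst_dataset(self._scenario(n_bursts=1500))
        h = build_histogram(detect_bursts(stream, threshold=20), neutral_setup)
        split = 0.55
        frac_lo = h.counts[h.centers < split].sum() / h.n_bursts
        assert frac_lo == pytest.approx(0.6, abs=0.05)

    def test_empty_retained_set_is_valid(self, neutral_setup):
        stream, _ = make_burst_dataset(
            self._scenario(n_bursts=100, donor_only_fraction=0.999)
        )
        h = build_histogram(detect_bursts(stream, threshold=20), neutral_setup)
        assert h.is_empty and h.counts.sum() == 0


class TestBurstVariance:
    def _static_bursts(self, n=400, e=0.4):
        spec = ScenarioSpec(
            populations=(Population("s", DistanceModel.fixed_efficiency(e), 1.0),),
            n_bursts=n,
            seed=11,
        )
        stream, _ = make_burst_dataset(spec)
        return detect_bursts(stream, threshold=30)

    def test_static_within_shot_noise_envelope(self):
        res = burst_variance_analysis(self._static_bursts(), window_photons=5)
        assert res.fraction_within_envelope(alpha=0.99) >= 0.95

    def test_dynamic_exchange_exceeds_envelope(self, neutral_setup):
        from fretscape import MarkovModel, SimConfig, simulate_photons

        # dwell ≈ 0.5 ms at a 1 ms burst: exchange on the burst timescale
        t_mat = np.array([[0.99, 0.01], [0.01, 0.99]])
        msm = MarkovModel(
            t_mat, lag_ns=10, efficiencies=np.array([0.15, 0.85]), rescale=500.0
        )
        stream, _ = simulate_photons(msm, neutral_setup, SimConfig(n_bursts=300, seed=5))
        bursts = detect_bursts(stream, threshold=30)
        res = burst_variance_analysis(bursts, window_photons=5)
        static = burst_variance_analysis(self._static_bursts(), window_photons=5)
        assert res.fraction_within_envelope(0.99) < 0.6
        # dynamics inflate the window spread well beyond its own shot-noise
        # expectation; static bursts sit at it
        dyn_ratio = (res.table["sd_e"] / res.table["expected_sd"]).mean()
        static_ratio = (static.table["sd_e"] / static.table["expected_sd"]).mean()
        assert dyn_ratio > 1.2
        assert static_ratio == pytest.approx(1.0, abs=0.1)

    def test_short_bursts_skipped_with_count(self):
        bursts = self._static_bursts(n=50)
        # window as large as the whole burst → a single window → skipped
        big = max(b.size for b in bursts)
        res = burst_variance_analysis(bursts, window_photons=big)
        assert res.n_skipped == len(bursts)
        assert len(res.table) == 0
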