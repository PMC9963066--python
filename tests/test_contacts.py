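"""Contact identification, set algebra, subpopulation boxing, correlation maps."""

import numpy as np
import pandas as pd
import pytest

from fretscape import (
    ConformerEnsemble,
    ContactDefinition,
    SubpopulationBoxes,
    assign_subpopulations,
    contact_classes,
    contact_query,
    make_toy_ensemble,
    pair_correlation_map,
    pair_distance_table,
    persistent_contacts,
    residue_com_contacts,
)


def _brute_force_contacts(coords, ids, cdef):
    out = set()
    n = len(ids)
    for a in range(n):
        for b in range(a + 1, n):
            if not (np.all(np.isfinite(coords[a])) and np.all(np.isfinite(coords[b]))):
                continue
            if np.linalg.norm(coords[a] - coords[b]) >= cdef.com_cutoff_angstrom:
                continue
            ri, rj = sorted((int(ids[a]), int(ids[b])))
            if rj - ri >= cdef.min_seq_sep:
                out.add((ri, rj))
    return out


class TestResidueContacts:
    def test_close_pair_with_sufficient_separation(self):
        coords = np.zeros((10, 3))
        coords[:, 0] = np.arange(10) * 10.0
        coords[8] = coords[1] + [2.9, 0, 0]  # residues 2 and 9: separation 7
        found = residue_com_contacts(coords, np.arange(1, 11), ContactDefinition())
        assert (2, 9) in found

    def test_close_pair_below_min_separation_excluded(self):
        coords = np.zeros((10, 3))
        coords[:, 0] = np.arange(10) * 10.0
        coords[6] = coords[1] + [2.9, 0, 0]  # residues 2 and 7: separation 5
        found = residue_com_contacts(coords, np.arange(1, 11), ContactDefinition())
        assert (2, 7) not in found

    def test_boundary_separation_six_is_included(self):
        coords = np.zeros((10, 3))
        coords[:, 0] = np.arange(10) * 10.0
        coords[7] = coords[1] + [2.0, 0, 0]  # residues 2 and 8: separation 6
        found = residue_com_contacts(coords, np.arange(1, 11), ContactDefinition())
        assert (2, 8) in found

    def test_cutoff_is_strict(self):
        coords = np.zeros((10, 3))
        coords[:, 0] = np.arange(10) * 10.0
        coords[9] = coords[0] + [3.0, 0, 0]  # exactly at the cutoff
        found = residue_com_contacts(coords, np.arange(1, 11), ContactDefinition())
        assert (1, 10) not in found

    def test_missing_coordinates_warn_and_exclude(self):
        coords = np.zeros((8, 3))
        coords[:, 0] = np.arange(8) * 10.0
        coords[3] = np.nan
        with pytest.warns(UserWarning, match="without coordinates"):
            found = residue_com_contacts(coords, np.arange(1, 9), ContactDefinition())
        assert all(4 not in pair for pair in found)

    def test_matches_brute_force_on_random_frames(self, rng):
        cdef = ContactDefinition(com_cutoff_angstrom=4.0, min_seq_sep=6)
        ids = np.arange(1, 101)
        for _ in range(200):
            coords = rng.uniform(0, 30, size=(100, 3))
            fast = residue_com_contacts(coords, ids, cdef)
            assert fast == _brute_force_contacts(coords, ids, cdef)


class TestPersistentContacts:
    def test_threshold_one_on_identical_frames(self):
        frame = np.zeros((20, 3))
        frame[:, 0] = np.arange(20) * 10.0
        frame[10] = frame[2] + [2.0, 0, 0]
        ens = ConformerEnsemble(np.repeat(frame[None], 5, axis=0), np.arange(1, 21))
        per_frame = residue_com_contacts(frame, ens.residue_ids, ContactDefinition())
        assert persistent_contacts(ens, persistence_threshold=1.0) == per_frame

    def test_planted_persistence_thresholds(self):
        ens = make_toy_ensemble(50, 40, planted_contacts=[(5, 25, 0.8)], seed=3)
        assert (5, 25) in persistent_contacts(ens, persistence_threshold=0.5)
        assert (5, 25) not in persistent_contacts(ens, persistence_threshold=0.9)

    def test_empty_frames_give_empty_set(self):
        coords = np.zeros((3, 10, 3))
        coords[:, :, 0] = np.arange(10) * 50.0
        ens = ConformerEnsemble(coords, np.arange(1, 11))
        assert persistent_contacts(ens, persistence_threshold=0.5) == set()

    def test_invalid_threshold(self):
        ens = make_toy_ensemble(20, 3, seed=0)
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                persistent_contacts(ens, persistence_threshold=bad)

    def test_frame_weights_drive_persistence(self):
        # contact only in frame 0; frame 0 carries 90% of the weight
        frame_a = np.zeros((20, 3))
        frame_a[:, 0] = np.arange(20) * 10.0
        frame_b = frame_a.copy()
        frame_a[10] = frame_a[2] + [2.0, 0, 0]
        ens = ConformerEnsemble(
            np.stack([frame_a, frame_b]), np.arange(1, 21), weights=[0.9, 0.1]
        )
        assert (3, 11) in persistent_contacts(ens, persistence_threshold=0.8)


class TestContactAlgebra:
    SETS = {
        "closed": {(1, 10), (2, 12), (3, 15)},
        "open": {(2, 12), (3, 15), (4, 20)},
        "extended": {(3, 15), (4, 20), (5, 30)},
    }

    def test_set_minus_itself_empty(self):
        assert contact_query(self.SETS, include=("open",), exclude=("open",)) == set()

    def test_hand_enumerated_queries(self):
        assert contact_query(self.SETS, include=("open", "closed")) == {(2, 12), (3, 15)}
        assert contact_query(self.SETS, include=("open",), exclude=("closed",)) == {(4, 20)}
        assert contact_query(self.SETS, include=("closed",), exclude=("open",)) == {(1, 10)}
        assert contact_query(
            self.SETS, include=("open", "extended"), exclude=("closed",)
        ) == {(4, 20)}

    def test_unknown_set_name(self):
        with pytest.raises(KeyError, match="unknown"):
            contact_query(self.SETS, include=("folded",))

    def test_identical_sets_all_shared(self):
        s = {(1, 10), (2, 20)}
        table = contact_classes({"a": s, "b": s, "c": s})
        assert set(table["class"]) == {"shared_all"}
        assert len(table) == 2

    def test_class_decomposition(self):
        table = contact_classes(self.SETS)
        by_pair = dict(zip(zip(table.res_i, table.res_j), table["class"]))
        assert by_pair[(3, 15)] == "shared_all"
        assert by_pair[(1, 10)] == "closed_only"
        assert by_pair[(5, 30)] == "extended_only"
        assert by_pair[(2, 12)] == "closed&open"
        assert by_pair[(4, 20)] == "open&extended"


class TestDistanceTable:
    def test_hand_computed_distances(self):
        coords = np.zeros((1, 3, 3))
        coords[0, 1] = [30.0, 40.0, 0.0]  # 50 Å from residue 1
        coords[0, 2] = [0.0, 0.0, 10.0]
        table = pair_distance_table(
            ConformerEnsemble(coords, [1, 2, 3]), [(1, 2), (1, 3)]
        )
        assert table.loc[0, "r_1_2"] == pytest.approx(5.0)  # nm
        assert table.loc[0, "r_1_3"] == pytest.approx(1.0)

    def test_zero_length_pair_rejected(self):
        ens = make_toy_ensemble(10, 2, seed=0)
        with pytest.raises(ValueError, match="zero-length"):
            pair_distance_table(ens, [(3, 3)])

    def test_column_order_follows_pair_order(self):
        ens = make_toy_ensemble(10, 2, seed=0)
        a = pair_distance_table(ens, [(1, 8), (2, 9)])
        b = pair_distance_table(ens, [(2, 9), (1, 8)])
        assert list(a.columns) == ["r_1_8", "r_2_9"]
        assert list(b.columns) == ["r_2_9", "r_1_8"]
        pd.testing.assert_series_equal(a["r_1_8"], b["r_1_8"])

    def test_unknown_residue_rejected(self):
        ens = make_toy_ensemble(10, 2, seed=0)
        with pytest.raises(ValueError, match="not in ensemble"):
            pair_distance_table(ens, [(1, 99)])


class TestSubpopulations:
    GEOM = {
        "labels": {"closed": 0.3, "open": 0.5, "extended": 0.2},
        "pairs": {
            (3, 30): {"closed": (0.5, 1.5), "open": (2.0, 3.5), "extended": (4.0, 6.0)},
            (8, 45): {"closed": (1.0, 2.0), "open": (2.5, 4.0), "extended": (4.5, 7.0)},
        },
    }
    BOXES = SubpopulationBoxes(
        plane=("r_3_30", "r_8_45"),
        boxes={
            "closed": (0.5, 1.5, 1.0, 2.0),
            "open": (2.0, 3.5, 2.5, 4.0),
            "extended": (4.0, 6.0, 4.5, 7.0),
        },
    )

    def test_overlapping_boxes_rejected_at_construction(self):
        with pytest.raises(ValueError, match="overlap"):
            SubpopulationBoxes(
                plane=("x", "y"),
                boxes={"a": (0, 2, 0, 2), "b": (1, 3, 1, 3)},
            )

    def test_planted_weights_recovered(self):
        ens = make_toy_ensemble(50, 500, subpopulation_geometry=self.GEOM, seed=21)
        table = pair_distance_table(ens, [(3, 30), (8, 45)])
        labels, weights = assign_subpopulations(table, self.BOXES)
        assert np.mean(labels.to_numpy() == ens.frame_labels) == 1.0
        for name, truth in self.GEOM["labels"].items():
            assert weights[name] == pytest.approx(truth, abs=0.06)

    def test_partition_covers_all_frames(self):
        ens = make_toy_ensemble(50, 120, subpopulation_geometry=self.GEOM, seed=22)
        table = pair_distance_table(ens, [(3, 30), (8, 45)])
        labels, weights = assign_subpopulations(table, self.BOXES)
        assert len(labels) == 120
        assert sum(weights.values()) == pytest.approx(1.0)

    def test_frame_outside_all_boxes_unassigned(self):
        table = pd.DataFrame({"r_3_30": [10.0], "r_8_45": [10.0]})
        labels, weights = assign_subpopulations(table, self.BOXES)
        assert labels.iloc[0] == "unassigned"
        assert weights["unassigned"] == pytest.approx(1.0)


class TestCorrelationMap:
    def test_marginals_equal_1d_histograms(self, rng):
        table = pd.DataFrame({"x": rng.normal(3, 1, 400), "y": rng.normal(5, 2, 400)})
        h, xe, ye = pair_correlation_map(table, "x", "y", grid=25)
        hx = np.histogram(table["x"], bins=xe)[0] / len(table)
        hy = np.histogram(table["y"], bins=ye)[0] / len(table)
        np.testing.assert_allclose(h.sum(axis=1), hx, atol=1e-12)
        np.testing.assert_allclose(h.sum(axis=0), hy, atol=1e-12)

    def test_independent_axes_give_product_density(self, rng):
        n = 40000
        table = pd.DataFrame({"x": rng.uniform(0, 1, n), "y": rng.uniform(0, 1, n)})
        h, *_ = pair_correlation_map(table, "x", "y", grid=5)
        np.testing.assert_allclose(h, np.full((5, 5), 1 / 25), atol=0.01)

    def test_perfectly_correlated_axes_mass_on_diagonal(self):
        x = np.linspace(0, 1, 100, endpoint=False)
        table = pd.DataFrame({"x": x, "y": x})
        edges = np.linspace(0, 1, 11)
        h, *_ = pair_correlation_map(table, "x", "y", grid=(edges, edges))
        assert np.trace(h) == pytest.approx(1.0)

    def test_degenerate_grid_rejected(self):
        table = pd.DataFrame({"x": [0.1], "y": [0.2]})
        with pytest.raises(ValueError, match="grid"):
            pair_correlation_map(table, "x", "y", grid=(np.array([1.0]), np.array([0, 1.0])))


class TestEnsembleIO:
    def test_pdb_round_trip_preserves_contacts(self, tmp_path):
        ens = make_toy_ensemble(40, 10, planted_contacts=[(4, 20, 1.0)], seed=5)
        path = tmp_path / "toy.pdb"
        ens.to_pdb(path)
        back = ConformerEnsemble.from_pdb(path)
        assert back.n_frames == 10 and back.n_residues == 40
        # PDB coordinates carry 3 decimals; contact sets survive rounding
        assert persistent_contacts(back, persistence_threshold=1.0) >= {(4, 20)}

    def test_heavy_atom_com_from_multiatom_pdb(self, tmp_path):
        # hand-built 2-residue, 2-model PDB with a hydrogen to be excluded
        text = "\n".join(
            [
                "MODEL        1",
                "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
                "ATOM      2  C   ALA A   1       2.000   0.000   0.000  1.00  0.00           C",
                "ATOM      3  H   ALA A   1      99.000   0.000   0.000  1.00  0.00           H",
                "ATOM      4  CA  GLY A   2       0.000   5.000   0.000  1.00  0.00           C",
                "ENDMDL",
                "MODEL        2",
                "ATOM      1  N   ALA A   1       0.000   0.000   2.000  1.00  0.00           N",
                "ATOM      2  C   ALA A   1       2.000   0.000   2.000  1.00  0.00           C",
                "ATOM      3  H   ALA A   1      99.000   0.000   2.000  1.00  0.00           H",
                "ATOM      4  CA  GLY A   2       0.000   5.000   2.000  1.00  0.00           C",
                "ENDMDL",
                "END",
            ]
        )
        path = tmp_path / "two_res.pdb"
        path.write_text(text + "\n")
        ens = ConformerEnsemble.from_pdb(path)
        # COM of N(14.007) at x=0 and C(12.011) at x=2 → x ≈ 0.9233
        expected_x = 2.0 * 12.011 / (14.007 + 12.011)
        assert ens.coords[0, 0, 0] == pytest.approx(expected_x, abs=1e-3)
        assert ens.coords[1, 0, 2] == pytest.approx(2.0)
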