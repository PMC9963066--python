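"""Conformational-ensemble analytics: contacts, subpopulations, correlations.

An ensemble is a stack of frames, each giving per-residue centre-of-mass
coordinates (Å).  Two residues are in contact in a frame when their centres
of mass are closer than a cutoff (default 3 Å) and they are separated in
sequence by at least a minimum number of residues (default 6, inclusive:
|j - i| = 6 counts).  Residue centres of mass are computed over heavy atoms.

On top of the per-frame contact sets this module provides

* persistent contacts — present in at least a (weighted) fraction of frames;
* set algebra over named contact sets (e.g. open ∩ closedᶜ) and the standard
  colour-class decomposition of two or three named ensembles;
* per-frame distance tables for chosen residue pairs (nm);
* subpopulation assignment by axis-aligned boxes in a distance-pair plane;
* weighted 2-D distance-pair correlation maps with exact marginals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ConformerEnsemble",
    "ContactDefinition",
    "SubpopulationBoxes",
    "residue_com_contacts",
    "persistent_contacts",
    "contact_query",
    "contact_classes",
    "pair_distance_table",
    "assign_subpopulations",
    "pair_correlation_map",
]

# heavy-atom masses (Da) for residue centre-of-mass computation
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

ANGSTROM_PER_NM = 10.0


@dataclass(frozen=True)
class ContactDefinition:
    """Centre-of-mass contact criterion.

    ``com_cutoff_angstrom``: residues are in contact when their centres of
    mass are strictly closer than this (default 3 Å).
    ``min_seq_sep``: minimum sequence separation |j - i| in residue
    numbering, inclusive (default 6: a pair six residues apart counts).
    """

    com_cutoff_angstrom: float = 3.0
    min_seq_sep: int = 6

    def __post_init__(self) -> None:
        if self.com_cutoff_angstrom <= 0:
            raise ValueError("contact cutoff must be positive")
        if self.min_seq_sep < 1:
            raise ValueError("sequence separation must be at least 1")


class ConformerEnsemble:
    """Per-frame per-residue centre-of-mass coordinates with optional weights.

    Parameters
    ----------
    coords_angstrom : (n_frames, n_residues, 3) array
        Residue centres of mass, Å.  NaN rows mark residues without
        coordinates in a frame (excluded from contact search with a warning).
    residue_ids : (n_residues,) array of int
        1-based residue numbering.
    weights : (n_frames,) array, optional
        Non-negative frame weights summing to one (uniform by default);
        typically the stationary populations of the Markov state model the
        frames were drawn from.
    """

    def __init__(self, coords_angstrom, residue_ids, weights=None) -> None:
        coords = np.asarray(coords_angstrom, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_residues, 3)")
        ids = np.asarray(residue_ids, dtype=np.int64)
        if len(ids) != coords.shape[1]:
            raise ValueError("one residue id per residue column required")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("residue ids must be unique")
        if weights is None:
            weights = np.full(coords.shape[0], 1.0 / coords.shape[0])
        weights = np.asarray(weights, dtype=float)
        if len(weights) != coords.shape[0]:
            raise ValueError("one weight per frame required")
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
        self.coords = coords
        self.residue_ids = ids
        self.weights = weights
        self._id_to_col = {int(r): i for i, r in enumerate(ids)}

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def column(self, residue_id: int) -> int:
        try:
            return self._id_to_col[int(residue_id)]
        except KeyError:
            raise ValueError(f"residue id {residue_id} not in ensemble") from None

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_pdb(cls, path: str | Path, heavy_only: bool = True) -> "ConformerEnsemble":
        """Read a multi-model PDB file; models become frames.

        Residue centres of mass are computed over heavy atoms (hydrogens
        excluded by default) with standard element masses.
        """
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
        atoms0 = stack[0]
        mask = np.ones(stack.shape[1], dtype=bool)
        if heavy_only:
            mask &= atoms0.element != "H"
        res_ids = np.unique(atoms0.res_id[mask])
        n_frames = stack.shape[0]
        coords = np.full((n_frames, len(res_ids), 3), np.nan)
        masses = np.array(
            [ATOMIC_MASSES.get(e.upper(), 12.011) for e in atoms0.element[mask]]
        )
        sel = stack.coord[:, mask, :]
        rid = atoms0.res_id[mask]
        for j, r in enumerate(res_ids):
            rm = rid == r
            w = masses[rm]
            coords[:, j, :] = (sel[:, rm, :] * w[None, :, None]).sum(axis=1) / w.sum()
        return cls(coords, res_ids)

    def to_pdb(self, path: str | Path) -> None:
        """Write the ensemble as a multi-model PDB of pseudo-CA atoms.

        Each residue is represented by a single alanine CA placed at its
        centre of mass — a round-trippable reduced representation for
        ensembles generated at residue level.
        """
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        n_res = self.n_residues
        atoms = struc.AtomArray(n_res)
        atoms.coord = self.coords[0]
        atoms.res_id = self.residue_ids
        atoms.res_name = np.full(n_res, "ALA")
        atoms.atom_name = np.full(n_res, "CA")
        atoms.element = np.full(n_res, "C")
        atoms.chain_id = np.full(n_res, "A")
        stack = struc.stack([atoms] * self.n_frames)
        stack.coord = self.coords.copy()
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))


def residue_com_contacts(
    frame_coords: np.ndarray,
    residue_ids: np.ndarray,
    cdef: ContactDefinition = ContactDefinition(),
) -> set[tuple[int, int]]:
    """Contact set of one frame: pairs (i, j), i < j, with COM distance
    strictly below the cutoff and sequence separation ≥ the minimum.

    Residues with missing (NaN) coordinates are excluded with a warning.
    Uses a KD-tree; equivalent to the O(n²) scan.
    """
    coords = np.asarray(frame_coords, dtype=float)
    ids = np.asarray(residue_ids, dtype=np.int64)
    ok = np.all(np.isfinite(coords), axis=1)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} residue(s) without coordinates excluded from contact search"
        )
    coords, ids = coords[ok], ids[ok]
    if len(coords) < 2:
        return set()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cdef.com_cutoff_angstrom, output_type="ndarray")
    out: set[tuple[int, int]] = set()
    for a, b in pairs:
        d = np.linalg.norm(coords[a] - coords[b])
        if d >= cdef.com_cutoff_angstrom:  # enforce strict inequality
            continue
        ri, rj = int(ids[a]), int(ids[b])
        if ri > rj:
            ri, rj = rj, ri
        if rj - ri >= cdef.min_seq_sep:
            out.add((ri, rj))
    return out


def persistent_contacts(
    ensemble: ConformerEnsemble,
    cdef: ContactDefinition = ContactDefinition(),
    persistence_threshold: float = 0.5,
) -> set[tuple[int, int]]:
    """Contacts present in at least ``persistence_threshold`` of the
    (weighted) frames."""
    if not 0 < persistence_threshold <= 1:
        raise ValueError("persistence threshold must lie in (0, 1]")
    occurrence: dict[tuple[int, int], float] = {}
    for f in range(ensemble.n_frames):
        w = ensemble.weights[f]
        for pair in residue_com_contacts(ensemble.coords[f], ensemble.residue_ids, cdef):
            occurrence[pair] = occurrence.get(pair, 0.0) + w
    # tolerance guards against float accumulation at exact thresholds
    return {p for p, occ in occurrence.items() if occ >= persistence_threshold - 1e-12}


# ----------------------------------------------------------------- set algebra


def contact_query(
    sets: dict[str, set], include: tuple[str, ...] = (), exclude: tuple[str, ...] = ()
) -> set:
    """Contacts in every ``include`` set and in no ``exclude`` set.

    E.g. ``contact_query(sets, include=("open",), exclude=("closed",))`` is
    open ∩ closedᶜ.
    """
    for name in (*include, *exclude):
        if name not in sets:
            raise KeyError(f"unknown contact-set name {name!r}")
    if not include:
        raise ValueError("need at least one set to include")
    out = set.intersection(*(sets[n] for n in include))
    for n in exclude:
        out -= sets[n]
    return out


def contact_classes(sets: dict[str, set]) -> pd.DataFrame:
    """Colour-class decomposition of named contact sets.

    Every contact appearing in any set is assigned the class naming exactly
    the sets that contain it, e.g. ``open&closed`` or ``open_only``.  A
    contact shared by all sets gets class ``shared_all``.  Returns a table
    with columns ``res_i``, ``res_j``, ``class``.
    """
    if not sets:
        raise ValueError("need at least one named contact set")
    names = list(sets)
    rows = []
    universe = set().union(*sets.values())
    for pair in sorted(universe):
        members = [n for n in names if pair in sets[n]]
        if len(members) == len(names) and len(names) > 1:
            label = "shared_all"
        elif len(members) == 1:
            label = f"{members[0]}_only"
        else:
            label = "&".join(members)
        rows.append({"res_i": pair[0], "res_j": pair[1], "class": label})
    return pd.DataFrame(rows, columns=["res_i", "res_j", "class"])


# -------------------------------------------------------------- distance pairs


def pair_distance_table(
    ensemble: ConformerEnsemble, residue_pairs: list[tuple[int, int]]
) -> pd.DataFrame:
    """Per-frame distances (nm) for chosen residue pairs.

    Columns are named ``r_<i>_<j>``; coordinates are converted from Å at
    this boundary.
    """
    cols = {}
    for i, j in residue_pairs:
        if i == j:
            raise ValueError(f"zero-length residue pair ({i}, {j}) rejected")
        a, b = ensemble.column(i), ensemble.column(j)
        d = np.linalg.norm(ensemble.coords[:, a, :] - ensemble.coords[:, b, :], axis=1)
        cols[f"r_{i}_{j}"] = d / ANGSTROM_PER_NM
    return pd.DataFrame(cols)


@dataclass
class SubpopulationBoxes:
    """Named, non-overlapping axis-aligned rectangles in a distance-pair plane.

    ``plane`` names the two table columns (e.g. ``("r_86_165", "r_86_241")``)
    and ``boxes`` maps a label to (x_lo, x_hi, y_lo, y_hi) in nm.
    """

    plane: tuple[str, str]
    boxes: dict[str, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        for name, (xl, xh, yl, yh) in self.boxes.items():
            if xl >= xh or yl >= yh:
                raise ValueError(f"box {name!r} has empty extent")
        for (na, a), (nb, b) in combinations(self.boxes.items(), 2):
            if a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]:
                raise ValueError(f"boxes {na!r} and {nb!r} overlap")

    def label_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        labels = np.full(len(x), "unassigned", dtype=object)
        for name, (xl, xh, yl, yh) in self.boxes.items():
            inside = (x >= xl) & (x < xh) & (y >= yl) & (y < yh)
            labels[inside] = name
        return labels


def assign_subpopulations(
    distance_table: pd.DataFrame,
    boxes: SubpopulationBoxes,
    weights: np.ndarray | None = None,
) -> tuple[pd.Series, dict[str, float]]:
    """Label every frame by the box containing it in the chosen plane.

    Returns per-frame labels (``"unassigned"`` outside all boxes) and the
    total frame weight per label; the weights over labels plus unassigned
    sum to 1.
    """
    for col in boxes.plane:
        if col not in distance_table.columns:
            raise ValueError(f"plane column {col!r} not in distance table")
    x = distance_table[boxes.plane[0]].to_numpy()
    y = distance_table[boxes.plane[1]].to_numpy()
    labels = pd.Series(boxes.label_points(x, y), index=distance_table.index, name="label")
    if weights is None:
        weights = np.full(len(labels), 1.0 / len(labels))
    w = pd.Series(np.asarray(weights, dtype=float), index=distance_table.index)
    totals = w.groupby(labels).sum().to_dict()
    for name in boxes.boxes:
        totals.setdefault(name, 0.0)
    totals.setdefault("unassigned", 0.0)
    return labels, totals


def pair_correlation_map(
    distance_table: pd.DataFrame,
    pair_x: str,
    pair_y: str,
    grid: int | tuple[np.ndarray, np.ndarray] = 50,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted 2-D density of one distance pair against another.

    Returns (density, x_edges, y_edges) with the density summing to 1; its
    marginals equal the corresponding weighted 1-D histograms exactly.
    """
    for col in (pair_x, pair_y):
        if col not in distance_table.columns:
            raise ValueError(f"column {col!r} not in distance table")
    x = distance_table[pair_x].to_numpy()
    y = distance_table[pair_y].to_numpy()
    if isinstance(grid, int):
        if grid < 1:
            raise ValueError("grid must have at least one bin")
        bins = grid
    else:
        xe, ye = (np.asarray(g, dtype=float) for g in grid)
        if len(xe) < 2 or len(ye) < 2 or np.any(np.diff(xe) <= 0) or np.any(np.diff(ye) <= 0):
            raise ValueError("degenerate grid: edges must be strictly increasing")
        bins = (xe, ye)
    h, x_edges, y_edges = np.histogram2d(x, y, bins=bins, weights=weights)
    total = h.sum()
    if total > 0:
        h = h / total
    return h, x_edges, y_edges
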