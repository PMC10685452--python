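"""Periodic-boundary geometry kernels: minimum-image distances and cell lists.

The contact statistic at the heart of the screening pipeline ("any heavy atom
within the cutoff of any heavy atom of the partner molecule") needs fixed-cutoff
neighbour queries under the minimum-image convention.  These are served by a
classic cell list whose cell edge is at least the cutoff, so only the 27
neighbouring cells of a query point have to be visited.

The contact boundary is CLOSED: a pair at exactly the cutoff distance counts.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model import Box

__all__ = [
    "min_image_displacement",
    "min_image_distance",
    "brute_force_min_distance",
    "CellList",
    "neighbor_any_within",
    "contact_molecule_pairs",
]


def min_image_displacement(p: np.ndarray, q: np.ndarray, box: Box) -> np.ndarray:
    """Minimum-image displacement vector(s) q - p, broadcasting over leading axes."""
    L = box.array
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    return d - L * np.round(d / L)


def min_image_distance(p: np.ndarray, q: np.ndarray, box: Box) -> float | np.ndarray:
    """Minimum over all periodic images of the Euclidean distance between p and q."""
    d = min_image_displacement(p, q, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def brute_force_min_distance(p: np.ndarray, q: np.ndarray, box: Box) -> float:
    """Explicit minimum over the 27 nearest image translations (test oracle)."""
    L = box.array
    shifts = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
        dtype=float,
    )
    d = np.asarray(q, float) - np.asarray(p, float) + shifts * L
    return float(np.min(np.linalg.norm(d, axis=1)))


class CellList:
    """Spatial hash over a periodic orthorhombic box for fixed-cutoff queries.

    The box is divided into ``n_c = floor(L / cutoff)`` cells per axis (at
    least one), so every cell edge is >= cutoff and any point within the
    cutoff of a query lies in one of the 27 cells around it (cells are
    revisited at most once when an axis has fewer than three cells).
    """

    def __init__(self, points: np.ndarray, cutoff: float, box: Box):
        if cutoff <= 0:
            raise ValueError("cutoff must be positive")
        box.check_cutoff(cutoff)
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3 or len(points) == 0:
            raise ValueError("points must be a non-empty (n, 3) array")
        self.box = box
        self.cutoff = float(cutoff)
        L = box.array
        self.n_cells = np.maximum(np.floor(L / cutoff).astype(int), 1)
        # wrap into the primary box before binning
        self.points = points - L * np.floor(points / L)
        cell_idx = np.floor(self.points / (L / self.n_cells)).astype(int)
        cell_idx = np.minimum(cell_idx, self.n_cells - 1)  # guard fp edge
        flat = np.ravel_multi_index(cell_idx.T, self.n_cells)
        order = np.argsort(flat, kind="stable")
        self._order = order
        self._flat_sorted = flat[order]
        # neighbour cell table: for each cell, the unique wrapped 27-neighbourhood
        self._neighbor_cache: dict[int, np.ndarray] = {}

    def _neighbor_cells(self, cell: np.ndarray) -> np.ndarray:
        key = int(np.ravel_multi_index(cell % self.n_cells, self.n_cells))
        hit = self._neighbor_cache.get(key)
        if hit is not None:
            return hit
        offsets = np.array(
            [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        )
        neigh = (cell + offsets) % self.n_cells
        flat = np.unique(np.ravel_multi_index(neigh.T, self.n_cells))
        self._neighbor_cache[key] = flat
        return flat

    def _candidate_indices(self, q: np.ndarray) -> np.ndarray:
        L = self.box.array
        qw = q - L * np.floor(q / L)
        cell = np.minimum(
            np.floor(qw / (L / self.n_cells)).astype(int), self.n_cells - 1
        )
        cand: list[np.ndarray] = []
        for flat in self._neighbor_cells(cell):
            lo = np.searchsorted(self._flat_sorted, flat, side="left")
            hi = np.searchsorted(self._flat_sorted, flat, side="right")
            if hi > lo:
                cand.append(self._order[lo:hi])
        if not cand:
            return np.empty(0, dtype=int)
        return np.concatenate(cand)

    def query_any(self, q: np.ndarray) -> bool:
        """True iff any stored point lies within the cutoff of q (closed boundary)."""
        idx = self._candidate_indices(np.asarray(q, float))
        if len(idx) == 0:
            return False
        d = min_image_distance(q, self.points[idx], self.box)
        return bool(np.any(d <= self.cutoff))

    def query_within(self, q: np.ndarray) -> np.ndarray:
        """Indices of stored points within the cutoff of q (closed boundary)."""
        idx = self._candidate_indices(np.asarray(q, float))
        if len(idx) == 0:
            return idx
        d = min_image_distance(q, self.points[idx], self.box)
        return idx[d <= self.cutoff]


def neighbor_any_within(
    group_a: Sequence[np.ndarray],
    group_b: np.ndarray,
    cutoff: float,
    box: Box,
) -> np.ndarray:
    """Per-molecule contact flags for group A against the atom cloud B.

    ``group_a`` is a sequence of per-molecule coordinate arrays; a molecule is
    flagged True iff ANY of its atoms is within ``cutoff`` (minimum image,
    closed boundary) of ANY atom of ``group_b``.
    """
    group_b = np.asarray(group_b, dtype=float)
    if len(group_a) == 0 or group_b.size == 0:
        raise ValueError("both atom groups must be non-empty")
    cells = CellList(group_b, cutoff, box)
    flags = np.zeros(len(group_a), dtype=bool)
    for m, mol in enumerate(group_a):
        mol = np.atleast_2d(np.asarray(mol, dtype=float))
        for atom in mol:
            if cells.query_any(atom):
                flags[m] = True
                break
    return flags


def contact_molecule_pairs(
    group_a: Sequence[np.ndarray],
    group_b: Sequence[np.ndarray],
    cutoff: float,
    box: Box,
) -> set[tuple[int, int]]:
    """All (i, j) with molecule i of A within cutoff of molecule j of B.

    Contacts are not exclusive: one A molecule may pair with several B
    molecules.  Uses one cell list over all B atoms.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both molecule groups must be non-empty")
    b_coords = np.concatenate([np.atleast_2d(np.asarray(m, float)) for m in group_b])
    if b_coords.size == 0:
        raise ValueError("group B has no atoms")
    b_mol = np.concatenate(
        [np.full(len(np.atleast_2d(m)), j, dtype=int) for j, m in enumerate(group_b)]
    )
    cells = CellList(b_coords, cutoff, box)
    pairs: set[tuple[int, int]] = set()
    for i, mol in enumerate(group_a):
        hit_mols: set[int] = set()
        for atom in np.atleast_2d(np.asarray(mol, float)):
            idx = cells.query_within(atom)
            if len(idx):
                hit_mols.update(b_mol[idx].tolist())
        pairs.update((i, j) for j in hit_mols)
    return pairs
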