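"""Domain model for annotated structures and trajectories.

All coordinates are stored in nanometres and all times in picoseconds.
Ångström values are converted at the PDB boundary.  Boxes are orthorhombic
only; triclinic input is rejected with an explicit error.

A *molecule* is a contiguous run of atoms sharing one ``molecule_id``; no
bond perception is attempted.  Detergent atoms may carry a ``head`` or
``tail`` role label (the hydrophilic vs. hydrophobic moiety); atoms of any
other molecule class always carry role ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

MOLECULE_CLASSES = ("protein", "lipid", "detergent", "solvent", "ion")
ROLES = ("head", "tail", "none")

#: elements treated as light (non-heavy) atoms
_LIGHT_ELEMENTS = {"H", "D"}


class UnsupportedBoxError(ValueError):
    """Raised for non-orthorhombic (triclinic) boxes."""


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box with extents in nm."""

    lengths: tuple[float, float, float]

    def __post_init__(self) -> None:
        lengths = tuple(float(x) for x in self.lengths)
        if len(lengths) != 3:
            raise ValueError("box needs exactly three extents")
        if not all(np.isfinite(lengths)) or min(lengths) <= 0:
            raise ValueError(f"box extents must be finite and > 0, got {lengths}")
        object.__setattr__(self, "lengths", lengths)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    @property
    def half_min_extent(self) -> float:
        return 0.5 * min(self.lengths)

    def check_cutoff(self, cutoff: float) -> None:
        """A minimum-image cutoff is only unambiguous below half the smallest extent."""
        if cutoff >= self.half_min_extent:
            raise ValueError(
                f"cutoff {cutoff} nm >= half the smallest box extent "
                f"({self.half_min_extent} nm): minimum-image distances are ambiguous"
            )

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, tol: float = 1e-6) -> "Box":
        """Build from a 3x3 box-vector matrix, rejecting triclinic cells."""
        m = np.asarray(matrix, dtype=float)
        off_diag = m - np.diag(np.diag(m))
        if np.max(np.abs(off_diag)) > tol:
            raise UnsupportedBoxError(
                "only orthorhombic boxes are supported; got a triclinic cell"
            )
        return cls(tuple(np.diag(m)))


def is_heavy(element: str, name: str = "") -> bool:
    """Heavy-atom test: element not H/D, with a name-based fallback.

    If the element string is empty, the first alphabetic character of the
    atom name decides (so "HB2" is light but "1H" is too, while "CA" is heavy).
    """
    el = element.strip()
    if el:
        return el.upper() not in _LIGHT_ELEMENTS
    for ch in name:
        if ch.isalpha():
            return ch.upper() not in _LIGHT_ELEMENTS
    return True


@dataclass(frozen=True)
class AtomRecord:
    atom_id: int
    name: str
    element: str
    is_heavy: bool
    molecule_id: int
    molecule_class: str
    species: str
    residue_index: int  # 1-based, protein only; 0 otherwise
    role: str = "none"

    def __post_init__(self) -> None:
        if self.atom_id < 1:
            raise ValueError("atom_id must be >= 1")
        if self.molecule_class not in MOLECULE_CLASSES:
            raise ValueError(
                f"unknown molecule_class {self.molecule_class!r}; "
                f"expected one of {MOLECULE_CLASSES}"
            )
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role != "none" and self.molecule_class != "detergent":
            raise ValueError(
                "head/tail roles are only valid on detergent atoms, "
                f"got role={self.role!r} on class {self.molecule_class!r}"
            )
        if self.molecule_class == "protein" and self.residue_index < 1:
            raise ValueError("protein atoms need residue_index >= 1")


class Topology:
    """Ordered atom records; the order defines the coordinate order of every Frame."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("topology must contain at least one atom")
        ids = [a.atom_id for a in atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("atom_ids must be unique")
        by_mol: dict[int, AtomRecord] = {}
        for a in atoms:
            ref = by_mol.setdefault(a.molecule_id, a)
            if (a.molecule_class, a.species) != (ref.molecule_class, ref.species):
                raise ValueError(
                    f"molecule {a.molecule_id} mixes classes/species: "
                    f"{(a.molecule_class, a.species)} vs "
                    f"{(ref.molecule_class, ref.species)}"
                )
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        self._index_cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    # --- selections (cached index arrays) ------------------------------

    def _cached(self, key: str, mask_fn) -> np.ndarray:
        if key not in self._index_cache:
            mask = np.fromiter((mask_fn(a) for a in self.atoms), dtype=bool, count=len(self.atoms))
            self._index_cache[key] = np.nonzero(mask)[0]
        return self._index_cache[key]

    def class_indices(self, molecule_class: str, heavy_only: bool = False) -> np.ndarray:
        key = f"class:{molecule_class}:{heavy_only}"
        return self._cached(
            key,
            lambda a: a.molecule_class == molecule_class and (a.is_heavy or not heavy_only),
        )

    def role_indices(self, role: str, heavy_only: bool = True) -> np.ndarray:
        key = f"role:{role}:{heavy_only}"
        return self._cached(key, lambda a: a.role == role and (a.is_heavy or not heavy_only))

    def molecule_ids_of(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray([self.atoms[i].molecule_id for i in indices], dtype=int)

    def molecules_of_class(self, molecule_class: str) -> list[int]:
        """Distinct molecule ids of a class, in topology order."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.molecule_class == molecule_class:
                seen.setdefault(a.molecule_id, None)
        return list(seen)

    def counts_by_class(self) -> dict[str, int]:
        """Number of molecules (not atoms) per class."""
        return {c: len(self.molecules_of_class(c)) for c in MOLECULE_CLASSES}

    def protein_residue_indices(self) -> np.ndarray:
        """Sorted distinct residue indices of protein atoms."""
        resi = sorted({a.residue_index for a in self.atoms if a.molecule_class == "protein"})
        return np.asarray(resi, dtype=int)


@dataclass
class Frame:
    """One time point: coordinates (nm) in topology order plus the periodic box."""

    time: float  # ps
    box: Box
    coords: np.ndarray  # (n_atoms, 3) nm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.topology)
        times = [f.time for f in self.frames]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        for f in self.frames:
            if len(f.coords) != n:
                raise ValueError(
                    f"frame at t={f.time} ps has {len(f.coords)} coordinates "
                    f"for {n} topology atoms"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.asarray([f.time for f in self.frames], dtype=float)

    def window(self, t0: float | None = None, t1: float | None = None) -> list[Frame]:
        """Frames with t0 <= time <= t1 (either bound optional)."""
        lo = -np.inf if t0 is None else t0
        hi = np.inf if t1 is None else t1
        return [f for f in self.frames if lo <= f.time <= hi]

    def second_half(self) -> list[Frame]:
        """Default analysis window: the last half of the frames."""
        return self.frames[len(self.frames) // 2:]
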