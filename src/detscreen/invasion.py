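"""Membrane-invasion statistics: detergent–lipid contact fractions.

A detergent molecule is "in contact" with the bilayer in a frame iff any of
its heavy atoms lies within the cutoff (default 0.6 nm, i.e. 6 Å, closed
boundary, minimum image) of any lipid heavy atom.  Two framings are
reported side by side, because both are used when screening detergents:

* the per-system total: percent of all detergent molecules in lipid contact,
  per frame and time-averaged;
* the per-lipid profile: for each lipid molecule, the time-averaged percent
  of detergent molecules in contact with *that* lipid, ranked from highest
  to lowest, plus the mean over lipids with its standard deviation across
  lipids as the error measure.

Contacts are not assigned exclusively — one detergent molecule may count
toward several lipids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import contact_molecule_pairs, neighbor_any_within
from .model import Frame, Topology, Trajectory

__all__ = [
    "InvasionResult",
    "ConvergenceReport",
    "molecule_atom_groups",
    "detergent_invasion_fraction",
    "per_lipid_detergent_profile",
    "checkpoint_convergence",
]

DEFAULT_CUTOFF_NM = 0.6


@dataclass
class InvasionResult:
    frame_times: np.ndarray  # ps
    per_frame_fraction: np.ndarray  # %
    mean_fraction: float  # %
    sd_fraction: float  # % (std over frames)
    cutoff: float  # nm
    n_frames_used: int
    # per-lipid part (filled by per_lipid_detergent_profile)
    per_lipid_profile: np.ndarray | None = None  # % sorted descending
    per_lipid_molecule_ids: np.ndarray | None = None  # lipid ids in profile order
    lipid_mean: float | None = None  # % mean over lipids
    lipid_sd: float | None = None  # % std over lipids

    def __post_init__(self) -> None:
        if np.any(self.per_frame_fraction < 0) or np.any(self.per_frame_fraction > 100):
            raise ValueError("fractions must lie in [0, 100] %")


@dataclass
class ConvergenceReport:
    checkpoint_times: np.ndarray  # ps
    checkpoint_values: np.ndarray
    max_pairwise_delta: float
    tolerance: float
    equilibrated: bool


def molecule_atom_groups(
    topology: Topology, molecule_class: str, heavy_only: bool = True
) -> tuple[list[int], list[np.ndarray]]:
    """Per-molecule atom index arrays for a class (topology order of molecules)."""
    groups: dict[int, list[int]] = {}
    for i, atom in enumerate(topology):
        if atom.molecule_class == molecule_class and (atom.is_heavy or not heavy_only):
            groups.setdefault(atom.molecule_id, []).append(i)
    mol_ids = list(groups)
    return mol_ids, [np.asarray(groups[m], dtype=int) for m in mol_ids]


def _select_frames(traj: Trajectory, window: tuple[float | None, float | None] | None) -> list[Frame]:
    frames = traj.second_half() if window is None else traj.window(*window)
    if not frames:
        raise ValueError("analysis window contains no frames")
    return frames


def _require_groups(traj: Trajectory, heavy_only: bool):
    det_ids, det_groups = molecule_atom_groups(traj.topology, "detergent", heavy_only)
    lip_ids, lip_groups = molecule_atom_groups(traj.topology, "lipid", heavy_only)
    if not det_groups:
        raise ValueError("trajectory contains no detergent molecules")
    if not lip_groups:
        raise ValueError("trajectory contains no lipid molecules")
    return det_ids, det_groups, lip_ids, lip_groups


def detergent_invasion_fraction(
    traj: Trajectory,
    cutoff: float = DEFAULT_CUTOFF_NM,
    window: tuple[float | None, float | None] | None = None,
    heavy_only: bool = True,
) -> InvasionResult:
    """Percent of detergent molecules in lipid contact, per frame and averaged.

    The default window is the second half of the trajectory.
    """
    _, det_groups, _, lip_groups = _require_groups(traj, heavy_only)
    frames = _select_frames(traj, window)
    frames[0].box.check_cutoff(cutoff)
    lip_atoms = np.concatenate(lip_groups)
    fractions = np.empty(len(frames))
    times = np.empty(len(frames))
    for k, frame in enumerate(frames):
        flags = neighbor_any_within(
            [frame.coords[g] for g in det_groups],
            frame.coords[lip_atoms],
            cutoff,
            frame.box,
        )
        fractions[k] = 100.0 * np.mean(flags)
        times[k] = frame.time
    return InvasionResult(
        frame_times=times,
        per_frame_fraction=fractions,
        mean_fraction=float(np.mean(fractions)),
        sd_fraction=float(np.std(fractions, ddof=0)),
        cutoff=cutoff,
        n_frames_used=len(frames),
    )


def per_lipid_detergent_profile(
    traj: Trajectory,
    cutoff: float = DEFAULT_CUTOFF_NM,
    window: tuple[float | None, float | None] | None = None,
    heavy_only: bool = True,
) -> InvasionResult:
    """Ranked per-lipid profile plus the total fraction, in one pass.

    For each lipid molecule the per-frame percent of detergent molecules with
    at least one heavy atom within the cutoff of that lipid is averaged over
    the window and the profile is sorted descending; ``lipid_mean`` and
    ``lipid_sd`` summarise it across lipids.
    """
    _, det_groups, lip_ids, lip_groups = _require_groups(traj, heavy_only)
    frames = _select_frames(traj, window)
    frames[0].box.check_cutoff(cutoff)
    n_det = len(det_groups)
    n_lip = len(lip_groups)
    counts = np.zeros(n_lip)  # summed per-frame detergent counts per lipid
    total = np.empty(len(frames))
    times = np.empty(len(frames))
    for k, frame in enumerate(frames):
        pairs = contact_molecule_pairs(
            [frame.coords[g] for g in det_groups],
            [frame.coords[g] for g in lip_groups],
            cutoff,
            frame.box,
        )
        per_lip = np.zeros(n_lip)
        contacting = set()
        for det_i, lip_j in pairs:
            per_lip[lip_j] += 1
            contacting.add(det_i)
        counts += per_lip
        total[k] = 100.0 * len(contacting) / n_det
        times[k] = frame.time
    profile = 100.0 * counts / (n_det * len(frames))
    order = np.argsort(-profile, kind="stable")
    return InvasionResult(
        frame_times=times,
        per_frame_fraction=total,
        mean_fraction=float(np.mean(total)),
        sd_fraction=float(np.std(total, ddof=0)),
        cutoff=cutoff,
        n_frames_used=len(frames),
        per_lipid_profile=profile[order],
        per_lipid_molecule_ids=np.asarray(lip_ids, dtype=int)[order],
        lipid_mean=float(np.mean(profile)),
        lipid_sd=float(np.std(profile, ddof=0)),
    )


def checkpoint_convergence(
    times: np.ndarray,
    values: np.ndarray,
    checkpoint_times: list[float],
    tolerance: float,
    k_last: int = 3,
) -> ConvergenceReport:
    """Windowed checkpoint means and an equilibration verdict.

    The value at checkpoint t is the mean of the metric over samples in
    (previous checkpoint, t] (from the series start for the first
    checkpoint); the series is equilibrated iff the maximum pairwise
    difference among the last ``k_last`` checkpoint values is <= tolerance.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) != len(values):
        raise ValueError("times and values must have equal length")
    cps = [float(t) for t in checkpoint_times]
    if len(cps) < 2:
        raise ValueError("need at least two checkpoints")
    if sorted(cps) != cps:
        raise ValueError("checkpoint times must be strictly increasing")
    if cps[-1] > times[-1]:
        raise ValueError(
            f"checkpoint {cps[-1]} ps lies beyond the series end ({times[-1]} ps)"
        )
    cp_values = []
    prev = -np.inf
    for t in cps:
        mask = (times > prev) & (times <= t)
        if not np.any(mask):
            raise ValueError(f"no samples in checkpoint window ({prev}, {t}] ps")
        cp_values.append(float(np.mean(values[mask])))
        prev = t
    cp_values = np.asarray(cp_values)
    last = cp_values[-k_last:]
    max_delta = float(np.max(last) - np.min(last))
    return ConvergenceReport(
        checkpoint_times=np.asarray(cps),
        checkpoint_values=cp_values,
        max_pairwise_delta=max_delta,
        tolerance=float(tolerance),
        equilibrated=max_delta <= tolerance,
    )
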