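"""Protein structural-stabilization scoring: superposition, RMSF and ΔRMSF.

The stabilization axis of the detergent screen asks how much a detergent
environment lets the protein fluctuate relative to its native-membrane
reference.  Per-residue RMSF is computed after least-squares rigid-body
superposition (Kabsch, reflection-excluded) of every frame onto a reference,
and ΔRMSF subtracts a membrane-equilibrated reference profile residue-wise;
a lower average ΔRMSF means stronger stabilization.

Representative-atom rule: the residue's Cα when present, otherwise the
centroid of its heavy atoms.  Fluctuation reference default: the iterated
mean structure (fit → recompute mean → refit, to a 1e-6 nm mean shift).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .model import AtomRecord, Frame, Trajectory

__all__ = [
    "SuperpositionResult",
    "RMSFProfile",
    "DeltaRMSFResult",
    "ProfileConvergenceReport",
    "kabsch_superpose",
    "residue_rmsf",
    "delta_rmsf",
    "rmsf_convergence",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3) proper rotation
    translation: np.ndarray  # (3,) nm
    rmsd: float  # nm, post-fit

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``reference``.

    Reflections are excluded by the usual determinant correction, so the
    returned rotation is always proper (det = +1).  Raises on fewer than
    three points or collinear/degenerate input where the optimum is
    ambiguous.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both have shape (n, 3)")
    n = len(mobile)
    if n < 3:
        raise ValueError("superposition needs at least three points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    mu_m = w @ mobile
    mu_r = w @ reference
    pm = mobile - mu_m
    pr = reference - mu_r
    cov = (pm * w[:, None]).T @ pr
    u, s, vt = np.linalg.svd(cov)
    # Rank-deficient covariance with two vanishing singular values means the
    # points are collinear and the rotation about that axis is arbitrary.
    scale = max(s[0], 1e-30)
    if s[1] / scale < 1e-9:
        raise ValueError("degenerate (collinear) point set: superposition is ambiguous")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = mu_r - rotation @ mu_m
    fitted = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.sum(w[:, None] * (fitted - reference) ** 2)))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


@dataclass
class RMSFProfile:
    residue_indices: np.ndarray
    rmsf: np.ndarray  # nm
    fit_selection: str
    representative: str
    n_frames_used: int

    def __post_init__(self) -> None:
        if len(self.residue_indices) != len(self.rmsf):
            raise ValueError("residue_indices and rmsf must have equal length")
        if np.any(self.rmsf < 0):
            raise ValueError("rmsf must be non-negative")


@dataclass
class DeltaRMSFResult:
    residue_indices: np.ndarray
    per_residue_delta: np.ndarray  # nm, detergent − reference
    average_delta: float  # nm; lower ⇒ stronger stabilization
    species: str = ""


@dataclass
class ProfileConvergenceReport:
    checkpoint_times: np.ndarray
    profiles: list[RMSFProfile]
    successive_max_delta: np.ndarray  # nm, one per checkpoint pair
    tolerance: float
    equilibrated: bool  # final pair below tolerance


FitSelection = Literal["heavy", "ca", "none"]
Reference = Literal["mean", "first"]


def _protein_atoms(traj: Trajectory) -> list[tuple[int, AtomRecord]]:
    atoms = [(i, a) for i, a in enumerate(traj.topology) if a.molecule_class == "protein"]
    if not atoms:
        raise ValueError("trajectory contains no protein atoms")
    return atoms


def _fit_indices(atoms: list[tuple[int, AtomRecord]], fit_selection: str) -> np.ndarray:
    if fit_selection == "heavy":
        idx = [i for i, a in atoms if a.is_heavy]
    elif fit_selection == "ca":
        idx = [i for i, a in atoms if a.name == "CA"]
    elif fit_selection == "none":
        return np.empty(0, dtype=int)
    else:
        raise ValueError(f"unknown fit_selection {fit_selection!r}")
    if len(idx) < 3:
        raise ValueError(f"fit selection {fit_selection!r} selects fewer than 3 atoms")
    return np.asarray(idx, dtype=int)


def _representative_map(atoms: list[tuple[int, AtomRecord]]) -> dict[int, np.ndarray]:
    """residue_index -> atom indices whose centroid represents the residue."""
    ca: dict[int, int] = {}
    heavy: dict[int, list[int]] = {}
    for i, a in atoms:
        heavy.setdefault(a.residue_index, [])
        if a.is_heavy:
            heavy[a.residue_index].append(i)
        if a.name == "CA":
            ca[a.residue_index] = i
    rep: dict[int, np.ndarray] = {}
    missing = []
    for resi in sorted(heavy):
        if resi in ca:
            rep[resi] = np.asarray([ca[resi]], dtype=int)
        elif heavy[resi]:
            rep[resi] = np.asarray(heavy[resi], dtype=int)
        else:
            missing.append(resi)
    if missing:
        raise ValueError(f"residues without a representative heavy atom: {missing}")
    return rep


def _fitted_representative_coords(
    frames: list[Frame],
    fit_idx: np.ndarray,
    rep: dict[int, np.ndarray],
    reference: np.ndarray | None,
) -> np.ndarray:
    """(n_frames, n_residues, 3) representative coordinates after fitting."""
    resis = sorted(rep)
    out = np.empty((len(frames), len(resis), 3))
    for t, frame in enumerate(frames):
        coords = frame.coords
        if len(fit_idx) and reference is not None:
            sup = kabsch_superpose(coords[fit_idx], reference)
            coords = sup.apply(coords)
        for r, resi in enumerate(resis):
            out[t, r] = coords[rep[resi]].mean(axis=0)
    return out


def residue_rmsf(
    traj: Trajectory,
    fit_selection: FitSelection = "heavy",
    reference: Reference | Frame = "mean",
    window: tuple[float | None, float | None] | None = None,
    max_iter: int = 10,
    mean_tol: float = 1e-6,
) -> RMSFProfile:
    """Per-residue RMSF after rigid-body superposition.

    RMSFᵢ = sqrt(mean over frames of |rᵢ(t) − ⟨rᵢ⟩|²) with rᵢ the residue's
    representative atom after fitting and ⟨rᵢ⟩ its post-fit time mean.  With
    ``reference="mean"`` the fit reference is iterated to self-consistency.
    ``window`` defaults to the full trajectory.
    """
    frames = traj.frames if window is None else traj.window(*window)
    if len(frames) < 2:
        raise ValueError("RMSF needs at least two frames in the window")
    atoms = _protein_atoms(traj)
    fit_idx = _fit_indices(atoms, fit_selection)
    rep = _representative_map(atoms)

    if isinstance(reference, Frame):
        ref_coords = reference.coords[fit_idx] if len(fit_idx) else None
    elif reference == "first":
        ref_coords = frames[0].coords[fit_idx] if len(fit_idx) else None
    elif reference == "mean":
        ref_coords = frames[0].coords[fit_idx] if len(fit_idx) else None
        if ref_coords is not None:
            for _ in range(max_iter):
                fitted = np.empty((len(frames), len(fit_idx), 3))
                for t, frame in enumerate(frames):
                    sup = kabsch_superpose(frame.coords[fit_idx], ref_coords)
                    fitted[t] = sup.apply(frame.coords[fit_idx])
                new_ref = fitted.mean(axis=0)
                shift = float(np.max(np.linalg.norm(new_ref - ref_coords, axis=1)))
                ref_coords = new_ref
                if shift < mean_tol:
                    break
    else:
        raise ValueError(f"unknown reference {reference!r}")

    rep_coords = _fitted_representative_coords(frames, fit_idx, rep, ref_coords)
    mean_pos = rep_coords.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((rep_coords - mean_pos) ** 2, axis=2), axis=0))
    return RMSFProfile(
        residue_indices=np.asarray(sorted(rep), dtype=int),
        rmsf=rmsf,
        fit_selection=fit_selection,
        representative="ca-or-heavy-centroid",
        n_frames_used=len(frames),
    )


def delta_rmsf(
    detergent_profile: RMSFProfile,
    reference_profile: RMSFProfile,
    species: str = "",
) -> DeltaRMSFResult:
    """Residue-wise ΔRMSF = detergent − reference, plus its residue average."""
    a = detergent_profile.residue_indices
    b = reference_profile.residue_indices
    if len(a) != len(b) or np.any(a != b):
        diff = sorted(set(a.tolist()) ^ set(b.tolist()))
        raise ValueError(f"residue sets differ; symmetric difference: {diff}")
    if detergent_profile.representative != reference_profile.representative:
        raise ValueError("profiles use different representative-atom rules")
    delta = detergent_profile.rmsf - reference_profile.rmsf
    return DeltaRMSFResult(
        residue_indices=a.copy(),
        per_residue_delta=delta,
        average_delta=float(np.mean(delta)),
        species=species,
    )


def rmsf_convergence(
    traj: Trajectory,
    checkpoint_times: list[float],
    tolerance: float,
    **rmsf_kwargs,
) -> ProfileConvergenceReport:
    """RMSF profiles on growing windows [start, tₖ] and their successive drift.

    The convergence metric for each checkpoint pair is the max over residues
    of |RMSF(tₖ) − RMSF(tₖ₋₁)|; the trajectory counts as equilibrated iff the
    final pair's drift is below the tolerance.
    """
    cps = [float(t) for t in checkpoint_times]
    if len(cps) < 2:
        raise ValueError("need at least two checkpoints")
    if sorted(cps) != cps:
        raise ValueError("checkpoint times must be strictly increasing")
    if cps[-1] > traj.frames[-1].time:
        raise ValueError(f"checkpoint {cps[-1]} ps beyond trajectory end")
    profiles = [
        residue_rmsf(traj, window=(None, t), **rmsf_kwargs) for t in cps
    ]
    deltas = np.asarray(
        [
            float(np.max(np.abs(p2.rmsf - p1.rmsf)))
            for p1, p2 in zip(profiles, profiles[1:])
        ]
    )
    return ProfileConvergenceReport(
        checkpoint_times=np.asarray(cps),
        profiles=profiles,
        successive_max_delta=deltas,
        tolerance=float(tolerance),
        equilibrated=bool(deltas[-1] <= tolerance),
    )
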