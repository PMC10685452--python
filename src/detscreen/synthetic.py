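"""Seeded toy-dynamics generators with closed-form expectations.

Real detergent-screening data comes from long all-atom MD runs; these
generators reproduce only the *statistical structure* the downstream analyses
assume, which is what makes them usable as exact test oracles:

* :func:`simulate_detergent_membrane` — single-particle Metropolis Monte
  Carlo of detergent particles in a square-well slab potential (the lipid
  "bilayer"), U = −ε inside the slab and 0 outside, periodic in all axes.
  Detailed balance gives the stationary slab occupancy in closed form:
  ``f_eq = h·e^ε / (h·e^ε + (Lz − h))`` for slab width h and box height Lz.
* :func:`simulate_protein_fluctuations` — per-residue, per-coordinate
  discrete Ornstein–Uhlenbeck dynamics around a reference structure, with
  stationary per-coordinate standard deviation σᵢ, hence an expected RMSF of
  ``σᵢ·√3`` per residue.
* :func:`place_regio_detergents` — head- and tail-labelled single-site
  detergent particles placed in contact with protein residues according to a
  per-region propensity table, with binomially computable expected
  per-residue contact occupancies.

All randomness derives from one integer seed through
``numpy.random.SeedSequence(seed, spawn_key=(k,))`` with a fixed stream index
per generator, so every trajectory is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import AtomRecord, Box, Frame, Topology, Trajectory

__all__ = [
    "MembraneSimParams",
    "ProteinSimParams",
    "RegioRange",
    "RegioParams",
    "simulate_detergent_membrane",
    "simulate_protein_fluctuations",
    "place_regio_detergents",
    "equilibrium_slab_fraction",
    "slab_occupancy_series",
    "block_standard_error",
    "expected_contact_probability",
    "spaced_reference_coords",
]

_STREAM = {"membrane": 0, "protein": 1, "regio": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM[stream],)))


# ---------------------------------------------------------------------------
# membrane invasion toy model
# ---------------------------------------------------------------------------


@dataclass
class MembraneSimParams:
    """Square-well slab Monte Carlo, sized after the screening simulations
    (12 nm cubic box, 80 lipids, 240 detergents, 3:1 detergent:lipid)."""

    box: Box = field(default_factory=lambda: Box((12.0, 12.0, 12.0)))
    slab_halfwidth: float = 2.0  # nm; slab = |z − z_center| <= h/2
    n_lipids: int = 80
    n_detergents: int = 240
    affinity: float = 2.0  # ε, well depth in kT
    step_size: float = 0.5  # nm, max per-axis displacement
    n_steps: int = 20000
    sample_every: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slab_width >= self.box.lengths[2]:
            raise ValueError("slab width h must be smaller than the box height Lz")
        if self.n_detergents < 1:
            raise ValueError("need at least one detergent particle")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")

    @property
    def slab_width(self) -> float:
        return 2.0 * self.slab_halfwidth

    @property
    def z_center(self) -> float:
        return 0.5 * self.box.lengths[2]


def equilibrium_slab_fraction(params: MembraneSimParams) -> float:
    """Closed-form stationary fraction of detergent particles inside the slab."""
    h = params.slab_width
    lz = params.box.lengths[2]
    w = h * np.exp(params.affinity)
    return float(w / (w + (lz - h)))


def _lipid_grid(params: MembraneSimParams) -> np.ndarray:
    """Static lipid pseudo-atoms on two square leaflet grids at z_c ± h/4."""
    n_upper = (params.n_lipids + 1) // 2
    n_lower = params.n_lipids - n_upper
    lx, ly, _ = params.box.lengths
    coords = []
    for n_leaf, z in (
        (n_upper, params.z_center + params.slab_halfwidth / 2.0),
        (n_lower, params.z_center - params.slab_halfwidth / 2.0),
    ):
        if n_leaf == 0:
            continue
        side = int(np.ceil(np.sqrt(n_leaf)))
        xs = (np.arange(side) + 0.5) * lx / side
        ys = (np.arange(side) + 0.5) * ly / side
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])[:n_leaf]
        coords.append(np.column_stack([pts, np.full(n_leaf, z)]))
    return np.concatenate(coords)


def simulate_detergent_membrane(params: MembraneSimParams) -> Trajectory:
    """Metropolis MC of non-interacting detergent particles in a slab well.

    Every sweep proposes, for each particle independently, a uniform
    displacement in the cube [−step, step]³ and accepts with probability
    min(1, e^{−ΔU}) where U = −ε inside the slab.  Because the particles do
    not interact, the per-particle moves can be carried out simultaneously
    without breaking detailed balance.
    """
    rng = _rng(params.seed, "membrane")
    lz = params.box.lengths[2]
    L = params.box.array
    lipids = _lipid_grid(params)
    n = params.n_detergents
    pos = rng.uniform(0.0, L, size=(n, 3))

    def inside(z: np.ndarray) -> np.ndarray:
        return np.abs(z - params.z_center) <= params.slab_halfwidth

    eps = params.affinity
    frames: list[Frame] = []

    def record(step: int, det_pos: np.ndarray) -> None:
        coords = np.vstack([lipids, det_pos])
        frames.append(Frame(time=float(step), box=params.box, coords=coords.copy()))

    record(0, pos)
    for step in range(1, params.n_steps + 1):
        prop = pos + rng.uniform(-params.step_size, params.step_size, size=(n, 3))
        prop -= L * np.floor(prop / L)
        d_u = -eps * (inside(prop[:, 2]).astype(float) - inside(pos[:, 2]).astype(float))
        accept = rng.random(n) < np.exp(-np.maximum(d_u, -50.0))
        pos = np.where(accept[:, None], prop, pos)
        if step % params.sample_every == 0:
            record(step, pos)

    records = []
    for i in range(len(lipids)):
        records.append(
            AtomRecord(
                atom_id=i + 1,
                name="P",
                element="P",
                is_heavy=True,
                molecule_id=i + 1,
                molecule_class="lipid",
                species="LIP",
                residue_index=0,
            )
        )
    for j in range(n):
        records.append(
            AtomRecord(
                atom_id=len(lipids) + j + 1,
                name="C1",
                element="C",
                is_heavy=True,
                molecule_id=len(lipids) + j + 1,
                molecule_class="detergent",
                species="DET",
                residue_index=0,
            )
        )
    return Trajectory(Topology(records), frames)


def slab_occupancy_series(traj: Trajectory, params: MembraneSimParams) -> np.ndarray:
    """Per-frame fraction of detergent particles inside the slab."""
    det_idx = traj.topology.class_indices("detergent")
    out = np.empty(len(traj.frames))
    for k, frame in enumerate(traj.frames):
        z = frame.coords[det_idx, 2]
        out[k] = np.mean(np.abs(z - params.z_center) <= params.slab_halfwidth)
    return out


def block_standard_error(series: np.ndarray, n_blocks: int = 10) -> float:
    """Block-averaged standard error of the mean of a correlated series."""
    series = np.asarray(series, dtype=float)
    n = len(series) // n_blocks
    if n < 1:
        raise ValueError("series too short for the requested number of blocks")
    blocks = series[: n * n_blocks].reshape(n_blocks, n).mean(axis=1)
    return float(np.std(blocks, ddof=1) / np.sqrt(n_blocks))


# ---------------------------------------------------------------------------
# protein fluctuation toy model
# ---------------------------------------------------------------------------


@dataclass
class ProteinSimParams:
    reference_coords: np.ndarray  # (n_residues, 3) nm
    sigma: np.ndarray  # per-residue stationary per-coordinate std, nm
    tau: float = 5.0  # correlation time in frames
    n_frames: int = 1000
    seed: int = 0
    box: Box = field(default_factory=lambda: Box((15.0, 15.0, 15.0)))

    def __post_init__(self) -> None:
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        if self.reference_coords.ndim != 2 or self.reference_coords.shape[1] != 3:
            raise ValueError("reference_coords must have shape (n_residues, 3)")
        sigma = np.asarray(self.sigma, dtype=float)
        n_res = len(self.reference_coords)
        if sigma.ndim == 1 and len(sigma) != n_res:
            raise ValueError(f"sigma has {len(sigma)} entries for {n_res} residues")
        self.sigma = np.broadcast_to(sigma, (n_res,)).copy()
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def simulate_protein_fluctuations(params: ProteinSimParams) -> Trajectory:
    """Stationary Ornstein–Uhlenbeck fluctuations around a reference structure.

    Each coordinate follows x ← x̄ + a(x − x̄) + σᵢ√(1−a²)·ξ with
    a = exp(−1/τ); the chain is started from its stationary distribution, so
    the expected RMSF of residue i is exactly σᵢ√3 from the first frame on.
    """
    rng = _rng(params.seed, "protein")
    n_res = len(params.reference_coords)
    a = np.exp(-1.0 / params.tau)
    noise_scale = params.sigma[:, None] * np.sqrt(1.0 - a * a)
    ref = params.reference_coords
    x = ref + params.sigma[:, None] * rng.standard_normal((n_res, 3))
    frames = [Frame(time=0.0, box=params.box, coords=x.copy())]
    for t in range(1, params.n_frames):
        x = ref + a * (x - ref) + noise_scale * rng.standard_normal((n_res, 3))
        frames.append(Frame(time=float(t), box=params.box, coords=x.copy()))

    records = [
        AtomRecord(
            atom_id=i + 1,
            name="CA",
            element="C",
            is_heavy=True,
            molecule_id=1,
            molecule_class="protein",
            species="PROT",
            residue_index=i + 1,
        )
        for i in range(n_res)
    ]
    return Trajectory(Topology(records), frames)


# ---------------------------------------------------------------------------
# head/tail regioselectivity toy model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegioRange:
    """Inclusive residue range with head/tail contact propensities in [0, 1]."""

    start: int
    end: int
    head_propensity: float
    tail_propensity: float

    def __post_init__(self) -> None:
        if self.end < self.start or self.start < 1:
            raise ValueError(f"invalid residue range [{self.start}, {self.end}]")
        for p in (self.head_propensity, self.tail_propensity):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"propensity {p} outside [0, 1]")


@dataclass
class RegioParams:
    reference_coords: np.ndarray  # (n_residues, 3) nm, ideally > 2·cutoff apart
    residue_ranges: Sequence[RegioRange]
    n_detergent_particles: int = 20  # split evenly into head- and tail-labelled
    contact_distance: float = 0.6  # nm
    n_frames: int = 1000
    seed: int = 0
    box: Box = field(default_factory=lambda: Box((15.0, 15.0, 15.0)))

    def __post_init__(self) -> None:
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        if not self.residue_ranges:
            raise ValueError("residue_ranges must not be empty")
        n_res = len(self.reference_coords)
        for r in self.residue_ranges:
            if r.end > n_res:
                raise ValueError(f"range [{r.start}, {r.end}] exceeds {n_res} residues")
        if self.n_detergent_particles < 0:
            raise ValueError("n_detergent_particles must be >= 0")

    @property
    def n_head(self) -> int:
        return (self.n_detergent_particles + 1) // 2

    @property
    def n_tail(self) -> int:
        return self.n_detergent_particles // 2


def _propensity_per_residue(params: RegioParams, role: str) -> np.ndarray:
    p = np.zeros(len(params.reference_coords))
    for r in params.residue_ranges:
        val = r.head_propensity if role == "head" else r.tail_propensity
        p[r.start - 1 : r.end] = val
    return p


def expected_contact_probability(params: RegioParams, role: str) -> np.ndarray:
    """Expected per-residue occupancy: P(>=1 role-labelled particle in contact).

    Each particle independently picks a uniformly random residue and makes
    contact with the range propensity of that residue, so for k particles the
    per-frame occupancy of residue i is 1 − (1 − pᵢ/n)ᵏ.
    """
    p = _propensity_per_residue(params, role)
    n_res = len(p)
    k = params.n_head if role == "head" else params.n_tail
    return 1.0 - (1.0 - p / n_res) ** k


def spaced_reference_coords(n_residues: int, spacing: float = 2.0,
                            box: Box | None = None) -> np.ndarray:
    """Residue pseudo-atoms on a cubic grid, mutually >= spacing apart."""
    box = box or Box((15.0, 15.0, 15.0))
    side = int(np.ceil(n_residues ** (1.0 / 3.0)))
    pts = []
    for i in range(side):
        for j in range(side):
            for k in range(side):
                pts.append((1.0 + spacing * i, 1.0 + spacing * j, 1.0 + spacing * k))
                if len(pts) == n_residues:
                    coords = np.asarray(pts)
                    if np.any(coords.max(axis=0) > box.array - 1.0):
                        raise ValueError("protein grid does not fit in the box")
                    return coords
    raise AssertionError("unreachable")


def place_regio_detergents(params: RegioParams) -> Trajectory:
    """Place head/tail-labelled particles in residue contact per the propensity table.

    Per frame and particle: a residue is drawn uniformly at random; with the
    propensity of that residue's range (for the particle's role) the particle
    is placed inside the contact sphere of the residue, otherwise it goes to
    a bulk position farther than the contact distance from every residue.
    """
    rng = _rng(params.seed, "regio")
    ref = params.reference_coords
    n_res = len(ref)
    p_head = _propensity_per_residue(params, "head")
    p_tail = _propensity_per_residue(params, "tail")
    roles = ["head"] * params.n_head + ["tail"] * params.n_tail
    props = [p_head if r == "head" else p_tail for r in roles]

    def bulk_position() -> np.ndarray:
        for _ in range(1000):
            pos = rng.uniform(0.0, params.box.array)
            d = np.linalg.norm(ref - pos, axis=1)
            if np.all(d > params.contact_distance * 1.5):
                return pos
        raise RuntimeError("could not place a bulk particle away from the protein")

    frames: list[Frame] = []
    for t in range(params.n_frames):
        det = np.empty((len(roles), 3))
        for k, p in enumerate(props):
            i = rng.integers(n_res)
            if rng.random() < p[i]:
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                radius = params.contact_distance * rng.random() ** (1.0 / 3.0)
                det[k] = ref[i] + radius * direction
            else:
                det[k] = bulk_position()
        coords = np.vstack([ref, det]) if len(roles) else ref.copy()
        frames.append(Frame(time=float(t), box=params.box, coords=coords))

    records = [
        AtomRecord(
            atom_id=i + 1,
            name="CA",
            element="C",
            is_heavy=True,
            molecule_id=1,
            molecule_class="protein",
            species="PROT",
            residue_index=i + 1,
        )
        for i in range(n_res)
    ]
    for k, role in enumerate(roles):
        records.append(
            AtomRecord(
                atom_id=n_res + k + 1,
                name="O1" if role == "head" else "C8",
                element="O" if role == "head" else "C",
                is_heavy=True,
                molecule_id=2 + k,
                molecule_class="detergent",
                species="DET",
                residue_index=0,
                role=role,
            )
        )
    return Trajectory(Topology(records), frames)
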