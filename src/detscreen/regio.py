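"""Head/tail regioselectivity of detergent–protein contacts.

Detergent molecules have a hydrophilic head and a hydrophobic tail; where
each moiety touches the protein distinguishes, e.g., a detergent coating the
transmembrane helices with its alkyl chains from one engaging surface loops
with its head groups.  The statistic reported per residue is the *occupancy*:
the fraction of frames in which at least one head-role (resp. tail-role)
heavy atom lies within the cutoff of any of the residue's heavy atoms
(minimum image, closed boundary).  Occupancy is robust to detergent copy
number, unlike raw contact counts.

Named regions (TM helices, loops) are user-supplied residue ranges, e.g. in
a flat TOML file::

    [regions.TM11]
    range = [380, 402]
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import CellList
from .model import Trajectory

__all__ = [
    "ContactMap",
    "RegionSummary",
    "headtail_contact_map",
    "region_contact_summary",
    "load_regions",
]

DEFAULT_CUTOFF_NM = 0.6


@dataclass
class ContactMap:
    residue_indices: np.ndarray
    head_occupancy: np.ndarray  # fraction of frames in [0, 1]
    tail_occupancy: np.ndarray
    cutoff: float  # nm
    n_frames: int

    def __post_init__(self) -> None:
        for occ in (self.head_occupancy, self.tail_occupancy):
            if np.any(occ < 0) or np.any(occ > 1):
                raise ValueError("occupancies must lie in [0, 1]")


@dataclass
class RegionSummary:
    names: list[str]
    ranges: list[tuple[int, int]]
    mean_head: np.ndarray
    mean_tail: np.ndarray
    head_tail_ratio: np.ndarray  # NaN where tail occupancy is 0 (undefined)


def headtail_contact_map(
    traj: Trajectory,
    cutoff: float = DEFAULT_CUTOFF_NM,
    window: tuple[float | None, float | None] | None = None,
) -> ContactMap:
    """Per-residue head and tail contact occupancies over the trajectory.

    ``window`` defaults to all frames.
    """
    topo = traj.topology
    residue_atoms: dict[int, list[int]] = {}
    for i, a in enumerate(topo):
        if a.molecule_class == "protein" and a.is_heavy:
            residue_atoms.setdefault(a.residue_index, []).append(i)
    if not residue_atoms:
        raise ValueError("trajectory contains no protein heavy atoms")
    head_idx = topo.role_indices("head", heavy_only=True)
    tail_idx = topo.role_indices("tail", heavy_only=True)
    if len(head_idx) == 0 and len(tail_idx) == 0:
        raise ValueError("no detergent atoms carry a head or tail role label")
    frames = traj.frames if window is None else traj.window(*window)
    if not frames:
        raise ValueError("analysis window contains no frames")
    frames[0].box.check_cutoff(cutoff)
    resis = sorted(residue_atoms)
    head_counts = np.zeros(len(resis))
    tail_counts = np.zeros(len(resis))
    for frame in frames:
        for idx, counts in ((head_idx, head_counts), (tail_idx, tail_counts)):
            if len(idx) == 0:
                continue
            cells = CellList(frame.coords[idx], cutoff, frame.box)
            for r, resi in enumerate(resis):
                for atom in residue_atoms[resi]:
                    if cells.query_any(frame.coords[atom]):
                        counts[r] += 1
                        break
    n = len(frames)
    return ContactMap(
        residue_indices=np.asarray(resis, dtype=int),
        head_occupancy=head_counts / n,
        tail_occupancy=tail_counts / n,
        cutoff=cutoff,
        n_frames=n,
    )


def load_regions(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read named residue ranges from a flat TOML regions file."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    out = {}
    for name, entry in data.get("regions", data).items():
        lo, hi = entry["range"]
        out[str(name)] = (int(lo), int(hi))
    return out


def region_contact_summary(
    contact_map: ContactMap,
    regions: dict[str, tuple[int, int]],
) -> RegionSummary:
    """Mean head/tail occupancy and head:tail ratio per named region.

    Ranges are inclusive, must not overlap and must stay within the map's
    residue index bounds.  The ratio is reported as NaN (undefined) for
    regions whose tail occupancy is zero.
    """
    if not regions:
        raise ValueError("no regions given")
    resis = contact_map.residue_indices
    lo_bound, hi_bound = int(resis.min()), int(resis.max())
    claimed: set[int] = set()
    names, ranges, mh, mt, ratio = [], [], [], [], []
    for name, (lo, hi) in regions.items():
        if lo > hi or lo < lo_bound or hi > hi_bound:
            raise ValueError(
                f"region {name!r} range [{lo}, {hi}] outside residue bounds "
                f"[{lo_bound}, {hi_bound}]"
            )
        span = set(range(lo, hi + 1))
        if span & claimed:
            raise ValueError(f"region {name!r} overlaps a previous region")
        claimed |= span
        mask = (resis >= lo) & (resis <= hi)
        if not np.any(mask):
            raise ValueError(f"region {name!r} contains no mapped residues")
        h = float(np.mean(contact_map.head_occupancy[mask]))
        t = float(np.mean(contact_map.tail_occupancy[mask]))
        names.append(name)
        ranges.append((lo, hi))
        mh.append(h)
        mt.append(t)
        ratio.append(h / t if t > 0 else np.nan)
    return RegionSummary(
        names=names,
        ranges=ranges,
        mean_head=np.asarray(mh),
        mean_tail=np.asarray(mt),
        head_tail_ratio=np.asarray(ratio),
    )
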