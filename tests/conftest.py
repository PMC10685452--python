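"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's cell-list and SVD code
paths: distances are minimised explicitly over the 27 nearest periodic image
translations and superpositions are solved with the quaternion eigenvector
method, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest

from detscreen.model import AtomRecord, Box, Frame, Topology, Trajectory

SHIFTS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
    dtype=float,
)


def _wrap(x: np.ndarray, box: Box) -> np.ndarray:
    L = box.array
    return x - L * np.floor(x / L)


def image_min_dist(p: np.ndarray, q: np.ndarray, box: Box) -> float:
    """Explicit minimum over the 27 nearest image translations.

    Points are wrapped into the primary box first, after which the 27
    neighbouring images are sufficient for the true minimum.
    """
    d = _wrap(np.asarray(q, float), box) - _wrap(np.asarray(p, float), box)
    d = d + SHIFTS * box.array
    return float(np.min(np.linalg.norm(d, axis=1)))


def pairwise_min_dists(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """(len(a), len(b)) matrix of 27-image minimum distances, vectorised."""
    a = _wrap(np.asarray(a, float), box)
    b = _wrap(np.asarray(b, float), box)
    d = b[None, :, None, :] - a[:, None, None, :] + SHIFTS[None, None, :, :] * box.array
    return np.min(np.linalg.norm(d, axis=-1), axis=-1)


def quaternion_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition RMSD via the Kearsley quaternion eigenproblem."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    sm, sp = y - x, y + x
    xm, ym, zm = sm.T
    xp, yp, zp = sp.T
    K = np.empty((4, 4))
    K[0, 0] = np.sum(xm**2 + ym**2 + zm**2)
    K[1, 1] = np.sum(xm**2 + yp**2 + zp**2)
    K[2, 2] = np.sum(xp**2 + ym**2 + zp**2)
    K[3, 3] = np.sum(xp**2 + yp**2 + zm**2)
    K[0, 1] = K[1, 0] = np.sum(yp * zm - ym * zp)
    K[0, 2] = K[2, 0] = np.sum(xm * zp - xp * zm)
    K[0, 3] = K[3, 0] = np.sum(xp * ym - xm * yp)
    K[1, 2] = K[2, 1] = np.sum(xm * ym - xp * yp)
    K[1, 3] = K[3, 1] = np.sum(xm * zm - xp * zp)
    K[2, 3] = K[3, 2] = np.sum(ym * zm - yp * zp)
    lam_min = np.linalg.eigvalsh(K)[0]
    return float(np.sqrt(max(lam_min, 0.0) / len(mobile)))


def single_site_topology(n_detergent: int, n_lipid: int) -> Topology:
    """One heavy pseudo-atom per molecule: lipids first, then detergents."""
    records = []
    for i in range(n_lipid):
        records.append(
            AtomRecord(i + 1, "P", "P", True, i + 1, "lipid", "LIP", 0)
        )
    for j in range(n_detergent):
        records.append(
            AtomRecord(
                n_lipid + j + 1, "C1", "C", True, n_lipid + j + 1,
                "detergent", "DET", 0,
            )
        )
    return Topology(records)


def single_site_trajectory(
    lipid_pos: np.ndarray,
    detergent_frames: list[np.ndarray],
    box: Box,
) -> Trajectory:
    """Static lipids plus per-frame detergent positions."""
    lipid_pos = np.atleast_2d(lipid_pos)
    topo = single_site_topology(len(np.atleast_2d(detergent_frames[0])), len(lipid_pos))
    frames = [
        Frame(time=float(t), box=box, coords=np.vstack([lipid_pos, np.atleast_2d(det)]))
        for t, det in enumerate(detergent_frames)
    ]
    return Trajectory(topo, frames)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
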