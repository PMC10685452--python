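"""Two-axis detergent classification and combined ranking.

A good solubilizing detergent must do two independent things: *invade* the
bilayer (high detergent–lipid contact fraction) and *stabilize* the
extracted protein (low average ΔRMSF).  The two axes are combined by rank
aggregation:

* ``invasion_rank`` — 1 for the highest invasion percentage;
* ``stability_rank`` — 1 for the lowest average ΔRMSF; exact ties share the
  mean of the tied ranks (standard mid-rank convention);
* ``combined_score = invasion_rank + stability_rank`` (lower is better),
  ties broken by the better stability rank, then lexicographic name.

Classification: an *invader* exceeds the invasion threshold (default 45 %),
a *stabilizer* has stability_rank ≤ ⌈n/2⌉; a detergent that is both is a
*solubilizer*, one that is neither is *poor*.  The 25 % boundary used to
annotate notably weak invaders is a reporting annotation only, not a second
classification gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "DetergentScore",
    "score_detergents",
    "scores_from_ranks",
    "classify_detergents",
    "classify_from_ranks",
    "rank_combined",
    "DEFAULT_INVASION_THRESHOLD_PCT",
    "POOR_INVADER_ANNOTATION_PCT",
]

DEFAULT_INVASION_THRESHOLD_PCT = 45.0
POOR_INVADER_ANNOTATION_PCT = 25.0

CLASSES = ("solubilizer", "invader-only", "stabilizer-only", "poor")


@dataclass
class DetergentScore:
    name: str
    invasion_mean: float  # %
    invasion_sd: float  # %
    avg_delta_rmsf: float  # nm
    invasion_rank: float  # 1 = highest invasion %
    stability_rank: float  # 1 = lowest avg ΔRMSF
    combined_score: float  # invasion_rank + stability_rank
    combined_rank: int = 0
    detergent_class: str = ""


def _check_metrics(invasion: dict[str, float], delta: dict[str, float]) -> list[str]:
    names = sorted(set(invasion) | set(delta))
    missing = [n for n in names if n not in invasion or n not in delta]
    if missing:
        raise ValueError(f"missing invasion or ΔRMSF metric for: {missing}")
    if not names:
        raise ValueError("no detergents to score")
    for n in names:
        if not (math.isfinite(invasion[n]) and math.isfinite(delta[n])):
            raise ValueError(f"non-finite metric for detergent {n!r}")
    return names


def score_detergents(
    invasion_mean: dict[str, float],
    avg_delta_rmsf: dict[str, float],
    invasion_sd: dict[str, float] | None = None,
    invasion_threshold: float = DEFAULT_INVASION_THRESHOLD_PCT,
) -> list[DetergentScore]:
    """Build fully ranked and classified scores from the two raw metrics.

    Returns one :class:`DetergentScore` per detergent, sorted by combined
    rank (best first).
    """
    names = _check_metrics(invasion_mean, avg_delta_rmsf)
    inv = np.asarray([invasion_mean[n] for n in names])
    dr = np.asarray([avg_delta_rmsf[n] for n in names])
    inv_rank = rankdata(-inv, method="average")
    stab_rank = rankdata(dr, method="average")
    scores = [
        DetergentScore(
            name=n,
            invasion_mean=float(inv[i]),
            invasion_sd=float((invasion_sd or {}).get(n, float("nan"))),
            avg_delta_rmsf=float(dr[i]),
            invasion_rank=float(inv_rank[i]),
            stability_rank=float(stab_rank[i]),
            combined_score=float(inv_rank[i] + stab_rank[i]),
        )
        for i, n in enumerate(names)
    ]
    _assign_classes(scores, invasion_threshold)
    return rank_combined(scores)


def _assign_classes(scores: list[DetergentScore], invasion_threshold: float) -> None:
    half = math.ceil(len(scores) / 2)
    for s in scores:
        invader = s.invasion_mean > invasion_threshold
        stabilizer = s.stability_rank <= half
        if invader and stabilizer:
            s.detergent_class = "solubilizer"
        elif invader:
            s.detergent_class = "invader-only"
        elif stabilizer:
            s.detergent_class = "stabilizer-only"
        else:
            s.detergent_class = "poor"


def classify_detergents(
    invasion_mean: dict[str, float],
    avg_delta_rmsf: dict[str, float],
    invasion_threshold: float = DEFAULT_INVASION_THRESHOLD_PCT,
) -> dict[str, str]:
    """Two-axis classes: invader ⇔ invasion % > threshold; stabilizer ⇔
    stability rank in the better half (≤ ⌈n/2⌉); solubilizer ⇔ both."""
    scores = score_detergents(invasion_mean, avg_delta_rmsf,
                              invasion_threshold=invasion_threshold)
    return {s.name: s.detergent_class for s in scores}


def scores_from_ranks(
    invasion_rank: dict[str, float],
    stability_rank: dict[str, float],
    invasion_mean: dict[str, float] | None = None,
) -> list[DetergentScore]:
    """Build scores from externally determined rank vectors (e.g. published
    orderings) rather than raw metrics, and return them combined-ranked."""
    names = sorted(set(invasion_rank) | set(stability_rank))
    missing = [n for n in names if n not in invasion_rank or n not in stability_rank]
    if missing:
        raise ValueError(f"missing a rank for: {missing}")
    nan = float("nan")
    scores = [
        DetergentScore(
            name=n,
            invasion_mean=(invasion_mean or {}).get(n, nan),
            invasion_sd=nan,
            avg_delta_rmsf=nan,
            invasion_rank=float(invasion_rank[n]),
            stability_rank=float(stability_rank[n]),
            combined_score=float(invasion_rank[n] + stability_rank[n]),
        )
        for n in names
    ]
    return rank_combined(scores)


def classify_from_ranks(
    invasion_mean: dict[str, float],
    stability_rank: dict[str, float],
    invasion_threshold: float = DEFAULT_INVASION_THRESHOLD_PCT,
) -> dict[str, str]:
    """Classification when stability is available as a rank vector only."""
    names = sorted(set(invasion_mean) | set(stability_rank))
    missing = [n for n in names if n not in invasion_mean or n not in stability_rank]
    if missing:
        raise ValueError(f"missing invasion % or stability rank for: {missing}")
    half = math.ceil(len(names) / 2)
    out = {}
    for n in names:
        invader = invasion_mean[n] > invasion_threshold
        stabilizer = stability_rank[n] <= half
        out[n] = (
            "solubilizer" if invader and stabilizer
            else "invader-only" if invader
            else "stabilizer-only" if stabilizer
            else "poor"
        )
    return out


def rank_combined(scores: list[DetergentScore]) -> list[DetergentScore]:
    """Order by combined score; ties broken by stability rank, then name.

    The ordering depends only on the two rank vectors, so it is invariant
    under any strictly monotone transform of the raw metrics.
    """
    if not scores:
        raise ValueError("no detergents to rank")
    ordered = sorted(scores, key=lambda s: (s.combined_score, s.stability_rank, s.name))
    for k, s in enumerate(ordered):
        s.combined_rank = k + 1
    return ordered
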