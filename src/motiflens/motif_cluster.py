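"""Redundancy collapsing of similar motifs.

Public motif databases carry many near-duplicate matrices (paralogous TFs,
updated versions of the same factor).  When the user selects no motifs,
the analysis runs with one representative per cluster of similar motifs.

Similarity between two matrices is the maximum, over all ungapped column
offsets and both orientations (the second matrix and its reverse
complement), of the Pearson correlation between the flattened frequency
columns of the overlap, requiring an overlap of at least
``min(5, min(L1, L2))`` columns.  Clustering is average-linkage
hierarchical on distance ``1 - similarity``, cut at a configurable height;
each cluster is represented by its most informative member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .motif_model import Background, Motif, UNIFORM_BG, information_content

__all__ = [
    "MotifCluster",
    "MotifDistanceMatrix",
    "cluster_motifs",
    "distance_matrix",
    "motif_similarity",
]


def _rc_frequencies(f: np.ndarray) -> np.ndarray:
    # reverse positions, swap A<->T and C<->G
    return f[::-1, ::-1]


def _corr(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su < 1e-12 or sv < 1e-12:
        return 1.0 if np.allclose(u, v) else 0.0
    return float(np.corrcoef(u, v)[0, 1])


def motif_similarity(m1: Motif, m2: Motif) -> float:
    """Best ungapped, orientation-aware column correlation in [-1, 1]."""
    f1 = np.asarray(m1.frequencies, dtype=float)
    best = -1.0
    min_overlap = min(5, min(m1.length, m2.length))
    for f2 in (np.asarray(m2.frequencies, dtype=float), _rc_frequencies(m2.frequencies)):
        L1, L2 = f1.shape[0], f2.shape[0]
        for offset in range(-(L2 - min_overlap), L1 - min_overlap + 1):
            a0, a1 = max(0, offset), min(L1, offset + L2)
            if a1 - a0 < min_overlap:
                continue
            u = f1[a0:a1].ravel()
            v = f2[a0 - offset : a1 - offset].ravel()
            best = max(best, _corr(u, v))
    return best


@dataclass
class MotifDistanceMatrix:
    motif_ids: list[str]
    distances: np.ndarray  # symmetric, zero diagonal, entries in [0, 2]


def distance_matrix(motifs: list[Motif]) -> MotifDistanceMatrix:
    n = len(motifs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.clip(1.0 - motif_similarity(motifs[i], motifs[j]), 0.0, 2.0)
    return MotifDistanceMatrix(motif_ids=[m.id for m in motifs], distances=d)


@dataclass
class MotifCluster:
    members: list[str]  # motif ids
    representative: str


def cluster_motifs(
    motifs: list[Motif],
    distance_cut: float = 0.2,
    background: Background = UNIFORM_BG,
) -> list[MotifCluster]:
    """Average-linkage clusters cut at ``distance_cut`` (corr >= 0.8 default).

    The representative of each cluster is the member with the highest
    information content (ties broken by lexicographic id).  Cluster order
    and membership are independent of motif input order.
    """
    if not motifs:
        raise ValueError("cluster_motifs needs at least one motif")
    # canonical order makes the linkage invariant to input order
    order = sorted(range(len(motifs)), key=lambda i: motifs[i].id)
    ordered = [motifs[i] for i in order]
    if len(ordered) == 1:
        return [MotifCluster(members=[ordered[0].id], representative=ordered[0].id)]
    dm = distance_matrix(ordered)
    labels = fcluster(
        linkage(squareform(dm.distances, checks=False), method="average"),
        t=distance_cut,
        criterion="distance",
    )
    groups: dict[int, list[Motif]] = {}
    for m, lab in zip(ordered, labels):
        groups.setdefault(int(lab), []).append(m)
    clusters = []
    for members in groups.values():
        rep = max(
            members,
            key=lambda m: (information_content(m.frequencies, background), m.id),
        )
        # highest IC wins; among equal-IC members the *lexicographically
        # smallest* id is the canonical representative
        best_ic = information_content(rep.frequencies, background)
        tied = sorted(
            m.id
            for m in members
            if abs(information_content(m.frequencies, background) - best_ic) < 1e-12
        )
        clusters.append(
            MotifCluster(members=sorted(m.id for m in members), representative=tied[0])
        )
    clusters.sort(key=lambda c: c.members[0])
    return clusters
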