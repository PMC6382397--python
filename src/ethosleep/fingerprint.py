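"""Behavioral fingerprints: time-resolved state distributions, Bhattacharyya
divergence and UPGMA dendrograms.

An animal's fingerprint is the empirical distribution over the three
behavioral states in each of the 96 quarter-hour zeitgeber intervals of the
day, averaged across recording days.  Two fingerprints are compared by the
mean over intervals of the Bhattacharyya distance

    BD_t = -ln( sum_x sqrt(p_t(x) q_t(x)) )

which is a divergence, not a metric: it is symmetric with BD(p,p)=0 but
violates the triangle inequality (disjoint supports give unbounded BD,
capped here at -ln(1e-6)).  The resulting matrix is clustered with
classical UPGMA — arithmetic-mean linkage weighted by cluster sizes, node
heights at half the merge distance, ties broken by the lexicographically
lowest leaf label for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import zt

__all__ = [
    "N_INTERVALS",
    "BD_EPS",
    "BehaviorDistribution",
    "FingerprintDistanceMatrix",
    "Dendrogram",
    "behavior_distribution",
    "bhattacharyya",
    "pairwise_distance",
    "upgma",
    "ternary_trajectory",
    "TERNARY_VERTICES",
]

N_INTERVALS = 96  # quarter hours in a day
BD_EPS = 1e-6  # BC floor; caps BD at -ln(eps) for disjoint supports


@dataclass
class BehaviorDistribution:
    """Per-quarter-hour probability triple over (quiescence, micromovement, walking)."""

    animal_id: str
    p: np.ndarray = field(repr=False)  # (96, 3)

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (N_INTERVALS, 3):
            raise ValueError(f"expected ({N_INTERVALS}, 3) distribution grid")
        if np.any(self.p < 0) or not np.allclose(self.p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must be probability distributions")


def behavior_distribution(
    minute_states, minute_t=None, lights_on_s: float = 0.0, animal_id: str = ""
) -> BehaviorDistribution:
    """Fraction of minutes per state in each quarter-hour interval.

    Minutes are pooled across all days present, so the result is the
    day-averaged distribution; requires at least one full day so that every
    interval is populated.
    """
    states = np.asarray(minute_states)
    if minute_t is None:
        minute_t = np.arange(len(states)) * 60.0
    bins = np.floor(zt(minute_t, lights_on_s) * 4).astype(int) % N_INTERVALS
    p = np.zeros((N_INTERVALS, 3))
    for b in range(N_INTERVALS):
        sel = bins == b
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"interval {b} has no minutes; need full days")
        for s in range(3):
            p[b, s] = np.count_nonzero(states[sel] == s) / n
    return BehaviorDistribution(animal_id=animal_id, p=p)


def bhattacharyya(p, q) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval Bhattacharyya coefficient and distance.

    Accepts single distributions (length-3) or (96, 3) grids; returns
    matching-shaped ``(BC, BD)`` with BD capped at ``-ln(BD_EPS)``.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    bc = np.clip(np.sqrt(p * q).sum(axis=-1), 0.0, 1.0)
    bd = -np.log(np.maximum(bc, BD_EPS))
    return bc.squeeze(), bd.squeeze()


@dataclass
class FingerprintDistanceMatrix:
    labels: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix/labels size mismatch")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")


def pairwise_distance(dists: list[BehaviorDistribution]) -> FingerprintDistanceMatrix:
    """Mean-over-intervals Bhattacharyya distance between every pair."""
    if len(dists) < 2:
        raise ValueError("need >= 2 animals")
    p = np.stack([d.p for d in dists])  # (n, 96, 3)
    s = np.sqrt(p)
    bc = np.clip(np.einsum("itx,jtx->ijt", s, s), 0.0, 1.0)
    bd = -np.log(np.maximum(bc, BD_EPS))
    d = bd.mean(axis=2)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return FingerprintDistanceMatrix(labels=[x.animal_id for x in dists], d=d)


@dataclass
class Dendrogram:
    """UPGMA tree: scipy-style merge list over leaf ids 0..n-1 then n, n+1, ..."""

    labels: list[str]
    merges: list[tuple[int, int, float, int]]  # (node_a, node_b, height, size)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cophenetic(self) -> np.ndarray:
        """Pairwise cophenetic distances (2 x merge height of the join)."""
        n = self.n_leaves
        members = {i: [i] for i in range(n)}
        d = np.zeros((n, n))
        nid = n
        for a, b, h, _ in self.merges:
            for i in members[a]:
                for j in members[b]:
                    d[i, j] = d[j, i] = 2.0 * h
            members[nid] = members.pop(a) + members.pop(b)
            nid += 1
        return d

    def cut(self, k: int) -> dict[str, int]:
        """Assign leaves to k clusters by undoing the last k-1 merges."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError("k out of range")
        n = self.n_leaves
        members = {i: [i] for i in range(n)}
        nid = n
        for a, b, _h, _ in self.merges[: n - k]:
            members[nid] = members.pop(a) + members.pop(b)
            nid += 1
        out = {}
        for c, (_, leaves) in enumerate(sorted(members.items())):
            for i in leaves:
                out[self.labels[i]] = c
        return out


def upgma(matrix: FingerprintDistanceMatrix) -> Dendrogram:
    """Classical UPGMA with size-weighted arithmetic-mean linkage.

    Ties are broken by the lexicographically lowest leaf label among the
    candidate pairs, so the tree is deterministic.
    """
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("need >= 2 leaves")
    if not np.all(np.isfinite(matrix.d)):
        raise ValueError("non-finite distances")

    # active clusters: id -> (size, sorted leaf-label key)
    dist = {}
    active = {}
    for i in range(n):
        active[i] = (1, (matrix.labels[i],))
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(matrix.d[i, j])

    merges = []
    nid = n
    while len(active) > 1:
        best = None
        for (i, j), dij in dist.items():
            key = (dij, tuple(sorted(active[i][1] + active[j][1])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, a, b = best
        d_ab = dist.pop((a, b) if (a, b) in dist else (b, a))
        sa, la = active.pop(a)
        sb, lb = active.pop(b)
        new_size = sa + sb
        merges.append((a, b, d_ab / 2.0, new_size))
        for c in list(active):
            da = dist.pop((min(a, c), max(a, c)))
            db = dist.pop((min(b, c), max(b, c)))
            dist[(min(nid, c), max(nid, c))] = (sa * da + sb * db) / new_size
        active[nid] = (new_size, tuple(sorted(la + lb)))
        nid += 1
    return Dendrogram(labels=list(matrix.labels), merges=merges)


#: 2-D vertices of the state simplex: quiescence, micromovement, walking
TERNARY_VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])


def ternary_trajectory(dist: BehaviorDistribution) -> np.ndarray:
    """Barycentric (ternary) coordinates of each quarter-hour distribution.

    The 96 points trace the daily behavioral trajectory in the state
    simplex; time along the trajectory is the fourth dimension.
    """
    return dist.p @ TERNARY_VERTICES
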