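"""Hierarchical clustering of win-count profiles and stability analysis.

Participants are compared by the Manhattan (L1) distance between their
win-fraction profiles — robust against the occasional outlier listener —
and agglomerated with the Ward minimum-variance criterion applied, via the
Lance–Williams recurrence, to the dissimilarities *as given* (the unsquared
"ward.D" convention of R's hclust).  That variant is implemented here
directly because it is the stated method of the analysis; the squared-input
"ward.D2" convention is available as an option.

A clustering with k groups is "stable" when it persists over a long span of
merge heights in the dendrogram; `stable_solutions` formalises that as the
lifetime of each k and ranks solutions by it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trial_design import WinProfile

__all__ = [
    "DistanceMatrix",
    "Linkage",
    "ClusterSolution",
    "manhattan_matrix",
    "ward_linkage",
    "cut_tree",
    "stable_solutions",
    "cluster_centroids",
]


def manhattan_matrix(profiles: list[WinProfile]) -> np.ndarray:
    """Pairwise L1 distances between participants' win-fraction vectors.

    Distances use win *fractions*, not raw counts: on the full design the two
    differ only by the constant appearance count (leaving the clustering
    unchanged) and fractions stay comparable across reduced designs.
    """
    if not profiles:
        raise ValueError("no profiles")
    grid = profiles[0].levels
    for p in profiles:
        if p.levels != grid:
            raise ValueError(
                f"profile level grids differ: {p.levels} vs {grid}"
            )
    F = np.array([p.fractions for p in profiles], dtype=float)
    if not np.all(np.isfinite(F)):
        bad = [p.participant_id for p, row in zip(profiles, F) if not np.all(np.isfinite(row))]
        raise ValueError(f"undefined win fractions (zero appearances) for: {bad}")
    D = np.abs(F[:, None, :] - F[None, :, :]).sum(axis=2)
    return D


@dataclass
class Linkage:
    """An agglomerative merge tree over n participants.

    Leaves carry ids 1..n; the i-th merge creates internal id n+i.  Each row
    of ``merges`` is (child_a, child_b, height, size) with child_a < child_b.
    """

    n: int
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        if len(self.merges) != self.n - 1:
            raise ValueError(f"expected {self.n - 1} merges, got {len(self.merges)}")

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])


@dataclass
class ClusterSolution:
    """A flat cut of the dendrogram into k clusters."""

    k: int
    labels: np.ndarray  # participant index -> cluster id in 0..k-1
    lifetime: float | None = None
    centroids: dict | None = None


def ward_linkage(D: np.ndarray, squared: bool = False) -> Linkage:
    """Agglomerate with Ward's criterion via the Lance–Williams recurrence.

    At every step the pair of clusters at minimal current dissimilarity is
    merged (ties broken by smallest lexicographic cluster ids) and distances
    to every other cluster k update as

        d(ij, k) = [(n_i + n_k) d(i,k) + (n_j + n_k) d(j,k) - n_k d(i,j)]
                   / (n_i + n_j + n_k).

    With ``squared=False`` (default) the recurrence runs on the
    dissimilarities exactly as supplied — the "ward.D" convention.  With
    ``squared=True`` inputs are squared first and merge heights reported as
    square roots — the "ward.D2" convention.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0) or np.any(np.diag(D) != 0):
        raise ValueError("distances must be non-negative with zero diagonal")

    work = D.copy() ** 2 if squared else D.copy()
    # cluster id -> (matrix slot, size); ids follow the 1..n / n+1..2n-1 scheme
    active: dict[int, int] = {i + 1: i for i in range(n)}
    sizes: dict[int, int] = {i + 1: 1 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []

    for step in range(n - 1):
        ids = sorted(active)
        best = None
        for ai in range(len(ids)):
            for bj in range(ai + 1, len(ids)):
                ci, cj = ids[ai], ids[bj]
                d = work[active[ci], active[cj]]
                if best is None or d < best[0] - 1e-12:
                    best = (d, ci, cj)
        d_merge, ci, cj = best
        new_id = n + step + 1
        si, sj = sizes[ci], sizes[cj]
        slot_i, slot_j = active[ci], active[cj]

        for ck in ids:
            if ck in (ci, cj):
                continue
            sk = sizes[ck]
            slot_k = active[ck]
            tot = si + sj + sk
            d_new = (
                (si + sk) * work[slot_i, slot_k]
                + (sj + sk) * work[slot_j, slot_k]
                - sk * d_merge
            ) / tot
            work[slot_i, slot_k] = work[slot_k, slot_i] = d_new

        del active[ci], active[cj]
        active[new_id] = slot_i
        sizes[new_id] = si + sj
        height = math.sqrt(d_merge) if squared else d_merge
        merges.append((ci, cj, float(height), si + sj))

    return Linkage(n=n, merges=merges)


def cut_tree(linkage: Linkage, k: int) -> np.ndarray:
    """Labels for the k-cluster cut (undo the last k-1 merges).

    Cluster ids are 0..k-1 in order of each cluster's smallest leaf.
    """
    n = linkage.n
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}]")
    parent = {}
    for step, (a, b, _, _) in enumerate(linkage.merges[: n - k]):
        new_id = n + step + 1
        parent[a] = new_id
        parent[b] = new_id

    def root(i: int) -> int:
        while i in parent:
            i = parent[i]
        return i

    roots = [root(i + 1) for i in range(n)]
    order: dict[int, int] = {}
    for r in roots:
        if r not in order:
            order[r] = len(order)
    labels = np.array([order[r] for r in roots])
    assert len(set(labels)) == k
    return labels


def stable_solutions(linkage: Linkage) -> list[tuple[int, float]]:
    """Rank cluster counts k by dendrogram lifetime, descending.

    lifetime(k) = height of the merge reducing k clusters to k-1, minus the
    height of the merge reducing k+1 to k.  The k = 2 solution is bounded
    above by the root merge height (the dendrogram's display range ends
    there); k runs over 2..n-1.
    """
    n = linkage.n
    h = linkage.heights  # h[m-1] = height of merge m; merge m leaves n-m clusters
    out = []
    for k in range(2, n):
        upper = h[n - k]      # merge reducing k -> k-1 clusters (merge n-k+1)
        lower = h[n - k - 1]  # merge reducing k+1 -> k clusters (merge n-k)
        out.append((k, float(upper - lower)))
    out.sort(key=lambda kv: (-kv[1], kv[0]))
    return out


def cluster_centroids(labels: np.ndarray, profiles: list[WinProfile]) -> dict:
    """Per-cluster mean win fraction and across-participant SD at each level.

    Singleton clusters report SD 0 at every level with ``singleton=True``.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(profiles):
        raise ValueError("labels must cover all profiles")
    grid = profiles[0].levels
    F = np.array([p.fractions for p in profiles], dtype=float)
    out = {}
    for c in sorted(set(labels.tolist())):
        rows = F[labels == c]
        singleton = rows.shape[0] == 1
        mean = rows.mean(axis=0)
        sd = np.zeros(rows.shape[1]) if singleton else rows.std(axis=0, ddof=1)
        out[int(c)] = {
            "levels": grid,
            "mean": mean,
            "sd": sd,
            "n": int(rows.shape[0]),
            "singleton": singleton,
        }
    return out
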