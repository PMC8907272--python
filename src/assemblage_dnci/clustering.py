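"""Cluster definition and validation for fossiliferous levels.

Levels are grouped by compositional similarity: Jaccard dissimilarity on
presence/absence, UPGMA (average-linkage) agglomeration, a deterministic
dendrogram cut (silhouette-maximising by default), removal of singleton
clusters (a cluster must contain more than one level), and ANOSIM
validation of the resulting partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.metrics import silhouette_score

from .exceptions import ConfigurationError, ValidationError
from .occurrence import IncidenceMatrix


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities in [0, 1] between levels."""

    values: np.ndarray
    level_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.level_ids)
        if self.values.shape != (n, n):
            raise ValidationError("dissimilarity matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 1e-12:
            raise ValidationError("dissimilarity diagonal must be zero")
        if self.values.min() < -1e-12 or self.values.max() > 1.0 + 1e-12:
            raise ValidationError("dissimilarities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.level_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def jaccard_matrix(m: IncidenceMatrix) -> DissimilarityMatrix:
    """Jaccard dissimilarity d = 1 - a/(a+b+c) between all level pairs,
    with a = shared presences and b, c the presences unique to each level."""
    if m.n_levels < 2:
        raise ValidationError("need at least 2 levels for a dissimilarity matrix")
    if (m.values.sum(axis=1) == 0).any():
        raise ValidationError("all-zero level row: Jaccard undefined")
    cond = pdist(m.values.astype(bool), metric="jaccard")
    return DissimilarityMatrix(squareform(cond), list(m.level_ids))


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass
class UPGMATree:
    """Average-linkage dendrogram in scipy linkage-matrix form.

    Row ``[a, b, h, s]`` merges clusters ``a`` and ``b`` (leaves are
    ``0..n-1``, internal nodes ``n..2n-2`` in merge order) at height ``h``
    into a cluster of ``s`` leaves.
    """

    linkage: np.ndarray
    leaf_labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> np.ndarray:
        """Partition into k clusters by undoing the last k-1 merges.

        Returns integer labels 1..k aligned with ``leaf_labels``, numbered
        by order of first appearance.
        """
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ConfigurationError(f"k must be in [1, {n}], got {k}")
        parent = list(range(2 * n - 1))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for step in range(n - k):
            a, b, _, _ = self.linkage[step]
            node = n + step
            parent[find(int(a))] = node
            parent[find(int(b))] = node
        roots: dict[int, int] = {}
        labels = np.empty(n, dtype=int)
        for leaf in range(n):
            r = find(leaf)
            if r not in roots:
                roots[r] = len(roots) + 1
            labels[leaf] = roots[r]
        return labels

    def to_newick(self) -> str:
        """Newick string; branch length = merge-height difference between a
        node and its parent (leaves sit at height 0)."""
        n = self.n_leaves

        def height(node: int) -> float:
            return 0.0 if node < n else float(self.linkage[node - n, 2])

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - height(node)
            if node < n:
                return f"{self.leaf_labels[node]}:{bl:.6g}"
            a, b = int(self.linkage[node - n, 0]), int(self.linkage[node - n, 1])
            h = height(node)
            return f"({render(a, h)},{render(b, h)}):{bl:.6g}"

        root = 2 * n - 2
        h = height(root)
        a, b = int(self.linkage[root - n, 0]), int(self.linkage[root - n, 1])
        return f"({render(a, h)},{render(b, h)});"


def upgma(d: DissimilarityMatrix) -> UPGMATree:
    """UPGMA agglomeration with a deterministic tie rule.

    The distance from a merged cluster to any other cluster is the
    size-weighted mean of its members' distances. When several pairs attain
    the minimal distance, the pair whose (smallest, largest) original-leaf
    representatives sort lexicographically first is merged, so the tree is
    reproducible across platforms.
    """
    n = d.n
    if n < 2:
        raise ValidationError("need at least 2 levels to build a tree")
    M = d.values.astype(float).copy()
    ids = list(range(n))          # scipy-style node ids of active clusters
    reps = list(range(n))         # smallest original leaf in each cluster
    sizes = [1] * n
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        m_cur = M.shape[0]
        iu, ju = np.triu_indices(m_cur, k=1)
        vals = M[iu, ju]
        mn = vals.min()
        ties = np.flatnonzero(vals == mn)
        best = min(
            ties,
            key=lambda t: (
                min(reps[iu[t]], reps[ju[t]]),
                max(reps[iu[t]], reps[ju[t]]),
            ),
        )
        i, j = int(iu[best]), int(ju[best])
        new_row = (sizes[i] * M[i] + sizes[j] * M[j]) / (sizes[i] + sizes[j])
        keep = [x for x in range(m_cur) if x not in (i, j)]
        Z[step] = [
            min(ids[i], ids[j]),
            max(ids[i], ids[j]),
            mn,
            sizes[i] + sizes[j],
        ]
        M = np.pad(M[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        M[-1, :-1] = new_row[keep]
        M[:-1, -1] = new_row[keep]
        new_rep = min(reps[i], reps[j])
        new_size = sizes[i] + sizes[j]
        ids = [ids[x] for x in keep] + [n + step]
        reps = [reps[x] for x in keep] + [new_rep]
        sizes = [sizes[x] for x in keep] + [new_size]
    return UPGMATree(Z, list(d.level_ids))


# ---------------------------------------------------------------------------
# Cluster assignment
# ---------------------------------------------------------------------------


@dataclass
class ClusteringResult:
    """A validated partition of levels into clusters of size >= 2."""

    tree: UPGMATree
    assignment: dict[str, int]
    k: int
    cut_k: int
    removed_levels: list[str] = field(default_factory=list)
    anosim_r: float | None = None
    anosim_p: float | None = None
    silhouette: float | None = None

    def cluster_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for lv, c in self.assignment.items():
            out.setdefault(c, []).append(lv)
        return out

    def to_dict(self) -> dict:
        sizes = {c: len(ms) for c, ms in sorted(self.cluster_members().items())}
        return {
            "k": self.k,
            "cut_k": self.cut_k,
            "cluster_sizes": sizes,
            "removed_levels": list(self.removed_levels),
            "anosim_r": None if self.anosim_r is None else round(self.anosim_r, 6),
            "anosim_p": None if self.anosim_p is None else round(self.anosim_p, 6),
            "silhouette": None if self.silhouette is None else round(self.silhouette, 6),
        }


def assign_clusters(
    tree: UPGMATree, d: DissimilarityMatrix, k: int | None = None
) -> ClusteringResult:
    """Cut the dendrogram into clusters and drop singletons.

    If ``k`` is omitted the cut maximising the mean silhouette width over
    k = 2..n-1 is chosen (ties -> smallest k), a deterministic stand-in for
    reading the dendrogram by eye. Clusters of size 1 are moved to
    ``removed_levels``; retained clusters are renumbered 1..k' by first
    appearance along the leaf order.
    """
    n = tree.n_leaves
    if tree.leaf_labels != d.level_ids:
        raise ValidationError("tree and dissimilarity matrix label mismatch")
    if n < 3:
        raise ValidationError("need at least 3 levels to define clusters")
    sil: float | None = None
    if k is not None:
        if not 2 <= k <= n - 1:
            raise ConfigurationError(f"k must be in [2, {n - 1}], got {k}")
        labels = tree.cut(k)
        chosen = k
    else:
        best: tuple[float, int] | None = None
        for kk in range(2, n):
            score = float(
                silhouette_score(d.values, tree.cut(kk), metric="precomputed")
            )
            if best is None or score > best[0] + 1e-12:
                best = (score, kk)
        assert best is not None
        sil, chosen = best
        labels = tree.cut(chosen)

    counts = np.bincount(labels)
    removed = [lv for lv, c in zip(d.level_ids, labels) if counts[c] < 2]
    renum: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for lv, c in zip(d.level_ids, labels):
        if counts[c] < 2:
            continue
        if c not in renum:
            renum[c] = len(renum) + 1
        assignment[lv] = renum[c]
    return ClusteringResult(
        tree=tree,
        assignment=assignment,
        k=len(renum),
        cut_k=chosen,
        removed_levels=removed,
        silhouette=sil,
    )


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


def anosim(
    d: DissimilarityMatrix,
    assignment: dict[str, int],
    n_perm: int = 9999,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Analysis of similarities.

    R = (mean rank of between-group dissimilarities - mean rank of
    within-group dissimilarities) / (N(N-1)/4), with mid-ranks for ties.
    The one-sided p-value comes from random label permutations with fixed
    group sizes: p = (1 + #{R_perm >= R_obs}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ConfigurationError("n_perm must be at least 99")
    rng = np.random.default_rng(rng)
    levels = [lv for lv in d.level_ids if lv in assignment]
    if len(levels) < 4:
        raise ValidationError("ANOSIM needs at least 4 assigned levels")
    groups = np.array([assignment[lv] for lv in levels])
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs at least 2 clusters")
    if counts.min() < 2:
        raise ValidationError("every cluster must have >= 2 levels (remove singletons first)")
    idx = [d.level_ids.index(lv) for lv in levels]
    sub = d.values[np.ix_(idx, idx)]
    N = len(levels)
    iu, ju = np.triu_indices(N, k=1)
    ranks = rankdata(sub[iu, ju])
    denom = N * (N - 1) / 4.0

    def r_stat(g: np.ndarray) -> float:
        within = g[iu] == g[ju]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    r_obs = r_stat(groups)
    hits = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(groups)) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return r_obs, p
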