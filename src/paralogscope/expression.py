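"""Expression-similarity analysis of duplicate gene pairs.

Replicate averaging, per-gene z-score normalization, cosine/Pearson pair
similarity, the four-way cosine x divergence classification, deterministic
clustering (average-linkage agglomeration initializing spherical k-means on
one-minus-cosine distance), and reciprocal cluster/gene matching between
two sets of profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .io import ExpressionTable

__all__ = [
    "ExpressionProfile",
    "PairExpressionStats",
    "Clustering",
    "ClusterMatch",
    "average_replicates",
    "zscore_rows",
    "cosine_similarity",
    "pearson_and_transform",
    "classify_quadrant",
    "hac_partition",
    "kmeans_hac",
    "clustering_cost",
    "match_clusters",
    "gene_best_match",
    "regress_expression_vs_constraint",
]


@dataclass(frozen=True)
class ExpressionProfile:
    """A z-scored per-gene expression vector over growth conditions."""

    gene_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class PairExpressionStats:
    gene1_id: str
    gene2_id: str
    cosine: float
    pearson_r: float
    transformed_r: Optional[float]  # None flags |R| = 1 ("infinite")
    quadrant: Optional[str] = None


@dataclass(frozen=True)
class Clustering:
    k: int
    assignments: dict[str, int]
    centroids: np.ndarray  # (k, n_conditions), unit rows


@dataclass(frozen=True)
class ClusterMatch:
    query: int
    library: int
    cosine: float
    mutual: bool


def average_replicates(table: ExpressionTable) -> np.ndarray:
    """Arithmetic mean over replicates -> (n_genes, n_conditions) matrix."""
    return table.values.mean(axis=2)


def zscore_rows(
    matrix: np.ndarray, gene_ids: Sequence[str]
) -> list[ExpressionProfile]:
    """Z-score each row with the sample (n-1) standard deviation.

    Output rows have mean 0 and sample variance 1; a constant row raises a
    ``ValueError`` naming the gene.
    """
    matrix = np.asarray(matrix, dtype=float)
    profiles = []
    for gid, row in zip(gene_ids, matrix):
        sd = row.std(ddof=1)
        if sd == 0:
            raise ValueError(f"gene {gid!r}: constant expression row (variance 0)")
        profiles.append(ExpressionProfile(gid, (row - row.mean()) / sd))
    return profiles


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def pearson_and_transform(u: np.ndarray, v: np.ndarray) -> tuple[float, Optional[float]]:
    """Pearson R and its log transform ln((1+R)/(1-R)).

    ``|R| = 1`` yields ``None`` for the transform (infinite), so downstream
    regressions can drop such records explicitly.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(u) != len(v) or len(u) < 3:
        raise ValueError("vectors must have equal length >= 3")
    if u.std() == 0 or v.std() == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    r = float(np.corrcoef(u, v)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-15:
        return r, None
    return r, math.log((1.0 + r) / (1.0 - r))


def classify_quadrant(cosine: float, divergence_pct: float) -> str:
    """Four-way split on cosine (> 0.5 high) and divergence (> 50% high).

    A: high cosine / low divergence; B: high cosine / high divergence;
    C: low cosine / low divergence; D: low cosine / high divergence.
    Boundaries (cosine = 0.5, divergence = 50) count as low.
    """
    if not -1.0 <= cosine <= 1.0:
        raise ValueError(f"cosine {cosine} outside [-1, 1]")
    if not 0.0 <= divergence_pct <= 100.0:
        raise ValueError(f"divergence {divergence_pct} outside [0, 100]")
    high_cos = cosine > 0.5
    high_div = divergence_pct > 50.0
    if high_cos:
        return "B" if high_div else "A"
    return "D" if high_div else "C"


# ---------------------------------------------------------------------------
# Clustering


def _unit_rows(matrix: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(matrix, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot cluster a zero profile")
    return matrix / norms


def _centroids_from_labels(unit: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    centroids = np.zeros((k, unit.shape[1]))
    for j in range(k):
        members = unit[labels == j]
        mean = members.mean(axis=0)
        norm = np.linalg.norm(mean)
        # degenerate cancellation: fall back to the first member
        centroids[j] = members[0] if norm == 0 else mean / norm
    return centroids


def hac_partition(profiles: Sequence[ExpressionProfile], k: int) -> Clustering:
    """Average-linkage agglomerative clustering on 1 - cosine distance.

    The dendrogram is cut to exactly ``k`` clusters; scipy's deterministic
    merge order makes the result reproducible.
    """
    n = len(profiles)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    unit = _unit_rows(np.vstack([p.values for p in profiles]))
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        dist = np.clip(1.0 - unit @ unit.T, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        tree = linkage(squareform(dist, checks=False), method="average")
        labels = cut_tree(tree, n_clusters=k).ravel()
    # relabel by first appearance for stable cluster indices
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap)
    labels = np.array([remap[lab] for lab in labels])
    return Clustering(
        k,
        {p.gene_id: int(lab) for p, lab in zip(profiles, labels)},
        _centroids_from_labels(unit, labels, k),
    )


def clustering_cost(
    profiles: Sequence[ExpressionProfile], clustering: Clustering
) -> float:
    """Total within-cluster 1 - cosine cost of an assignment."""
    unit = _unit_rows(np.vstack([p.values for p in profiles]))
    labels = np.array([clustering.assignments[p.gene_id] for p in profiles])
    return float(np.sum(1.0 - np.sum(unit * clustering.centroids[labels], axis=1)))


def kmeans_hac(
    profiles: Sequence[ExpressionProfile],
    k: int = 16,
    max_iter: int = 300,
) -> Clustering:
    """Spherical k-means initialized from :func:`hac_partition` centroids.

    Distance is 1 - cosine; centroids are normalized means of (normalized)
    members.  Iterates to an assignment fixpoint (or ``max_iter``) with
    deterministic tie-breaking (lowest index), so repeat runs are
    bit-identical.  An emptied cluster is re-seeded with the point farthest
    from its current centroid.
    """
    n = len(profiles)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    unit = _unit_rows(np.vstack([p.values for p in profiles]))
    centroids = hac_partition(profiles, k).centroids.copy()
    labels = None
    for _ in range(max_iter):
        sims = unit @ centroids.T
        new_labels = np.argmax(sims, axis=1)  # ties -> lowest index
        # re-seed emptied clusters with the worst-fit point (deterministic)
        for j in range(k):
            if not np.any(new_labels == j):
                fit = sims[np.arange(n), new_labels]
                candidates = np.flatnonzero(
                    np.bincount(new_labels, minlength=k)[new_labels] > 1
                )
                far = candidates[np.argmin(fit[candidates])]
                new_labels[far] = j
                centroids[j] = unit[far]
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        centroids = _centroids_from_labels(unit, labels, k)
    return Clustering(
        k,
        {p.gene_id: int(lab) for p, lab in zip(profiles, labels)},
        centroids,
    )


def match_clusters(
    query: Clustering, library: Clustering
) -> tuple[list[ClusterMatch], float, Optional[float]]:
    """Best-cosine library centroid for each query centroid.

    A match is mutual when the two centroids are reciprocally each other's
    best match.  Returns the matches plus the mean and sample sd of the
    per-query best cosines (sd ``None`` for a single query cluster).
    """
    sims = query.centroids @ library.centroids.T
    best_for_query = np.argmax(sims, axis=1)
    best_for_library = np.argmax(sims, axis=0)
    matches = [
        ClusterMatch(
            query=i,
            library=int(j),
            cosine=float(sims[i, j]),
            mutual=bool(best_for_library[j] == i),
        )
        for i, j in enumerate(best_for_query)
    ]
    cosines = [m.cosine for m in matches]
    sd = float(np.std(cosines, ddof=1)) if len(cosines) > 1 else None
    return matches, float(np.mean(cosines)), sd


def gene_best_match(
    set_a: Sequence[ExpressionProfile], set_b: Sequence[ExpressionProfile]
) -> tuple[dict[str, float], float, Optional[float]]:
    """For each gene in ``set_a``, the max cosine over ``set_b``.

    Returns the per-gene best cosines plus their mean and sample sd.
    """
    if not set_a or not set_b:
        raise ValueError("both profile sets must be nonempty")
    unit_a = _unit_rows(np.vstack([p.values for p in set_a]))
    unit_b = _unit_rows(np.vstack([p.values for p in set_b]))
    sims = unit_a @ unit_b.T
    best = sims.max(axis=1)
    per_gene = {p.gene_id: float(s) for p, s in zip(set_a, best)}
    sd = float(np.std(best, ddof=1)) if len(best) > 1 else None
    return per_gene, float(best.mean()), sd


def regress_expression_vs_constraint(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float, float]:
    """Ordinary least squares y on x -> (slope, intercept, R, p).

    p is the two-sided t-distribution p-value of R with n - 2 df.
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate (zero-variance) sample")
    res = stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue),
        float(res.pvalue),
    )
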