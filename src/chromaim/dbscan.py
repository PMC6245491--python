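"""Stage 2: outlier-based SNP selection via density clustering.

Each Stage-1 SNP becomes an integer vector over the training samples: the
16 ordered genotype symbols {AA, AC, ..., TT} map lexicographically to
1..16 and masked (homozygous-reference) samples to 0.  DBSCAN with Euclidean
distance groups SNPs carrying similar ancestry information; the *outliers*
— SNPs too distinctive to join any cluster — are the candidates passed on
to correlation-based selection.

The clustering is implemented here from first principles (exact pairwise
distances, deterministic seed-point order) rather than delegated, because
its exact outlier semantics are the point of the stage; scikit-learn's
DBSCAN serves only as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

from .preprocess import MaskedVariant

#: ordered genotype symbol -> integer code, AA=1 ... TT=16
SYMBOL_TO_CODE: dict[tuple[str, str], int] = {
    (a, b): i for i, (a, b) in enumerate(product("ACGT", repeat=2), start=1)
}
CODE_TO_SYMBOL = {v: k for k, v in SYMBOL_TO_CODE.items()}

#: label given to points in no cluster
OUTLIER = -1


@dataclass
class CodeMatrix:
    """Rows = SNPs, columns = training samples, entries in {0,...,16}."""

    snp_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or len(self.snp_ids) != self.values.shape[0]:
            raise ValueError("code matrix shape does not match snp_ids")


def encode_symbols(
    variants: Sequence[MaskedVariant],
    sample_ids: list[str],
    training_ids: list[str],
) -> CodeMatrix:
    """Encode masked variants as the integer data matrix D (one row per SNP)."""
    col_of = {sid: j for j, sid in enumerate(training_ids)}
    values = np.zeros((len(variants), len(training_ids)), dtype=np.int16)
    for i, mv in enumerate(variants):
        for sid, keep, gt in zip(sample_ids, mv.retained, mv.record.genotypes):
            j = col_of.get(sid)
            if j is None or not keep:
                continue
            try:
                values[i, j] = SYMBOL_TO_CODE[gt]
            except KeyError:
                raise ValueError(f"{mv.rsid}: symbol {gt!r} outside {{A,C,G,T}}^2")
    return CodeMatrix(snp_ids=[mv.rsid for mv in variants], values=values)


class SnpDBSCAN(BaseEstimator, ClusterMixin):
    """Density-based clustering with noise, in the classic formulation.

    A *core* point has at least ``min_pts`` points (itself included) within
    Euclidean distance ``eps``; clusters are the maximal density-connected
    sets grown from core points in input order, and unassigned points are
    labelled :data:`OUTLIER` (-1).  Cluster labels start at 1.

    With ``min_pts=2``, a point is core iff it has one distinct neighbour
    within ``eps``; on integer code matrices with ``eps < 1`` the clusters
    are therefore exactly the groups of identical rows of multiplicity >= 2.

    Parameters
    ----------
    eps : float, default 0.1
        Neighbourhood radius (Euclidean).  The default is the operating
        point chosen empirically for the 26-population task.
    min_pts : int, default 2
        Minimum neighbourhood size (the point itself counts) for a core
        point.
    """

    def __init__(self, eps: float = 0.1, min_pts: int = 2):
        self.eps = eps
        self.min_pts = min_pts

    def fit(self, X, y=None) -> "SnpDBSCAN":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.eps < 0 or self.min_pts < 1:
            raise ValueError("require eps >= 0 and min_pts >= 1")
        n = X.shape[0]
        labels = np.full(n, 0, dtype=int)  # 0 = unvisited, OUTLIER, or 1..k
        visited = np.zeros(n, dtype=bool)
        # exact pairwise distances; chunked to bound memory at scale
        neighbors: list[np.ndarray] = []
        chunk = max(1, int(2**26 // max(1, n)))
        for start in range(0, n, chunk):
            d = cdist(X[start : start + chunk], X)
            for row in d:
                neighbors.append(np.flatnonzero(row <= self.eps))
        core = np.array([len(nb) >= self.min_pts for nb in neighbors], dtype=bool)
        cluster = 0
        for p in range(n):
            if visited[p]:
                continue
            visited[p] = True
            if not core[p]:
                labels[p] = OUTLIER
                continue
            cluster += 1
            labels[p] = cluster
            seeds = list(neighbors[p])
            i = 0
            while i < len(seeds):
                q = seeds[i]
                i += 1
                if not visited[q]:
                    visited[q] = True
                    if core[q]:
                        seeds.extend(neighbors[q])
                if labels[q] in (0, OUTLIER):
                    labels[q] = cluster
        self.labels_ = labels
        self.core_sample_indices_ = np.flatnonzero(core)
        self.n_clusters_ = cluster
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def dbscan(matrix: CodeMatrix, eps: float, min_pts: int) -> np.ndarray:
    """Cluster the code matrix rows; returns per-SNP labels (OUTLIER = -1)."""
    if matrix.values.shape[0] == 0:
        return np.empty(0, dtype=int)
    return SnpDBSCAN(eps=eps, min_pts=min_pts).fit_predict(matrix.values)


def select_outliers(matrix: CodeMatrix, labels: np.ndarray) -> list[str]:
    """SNP ids labelled as outliers, in input (genomic) order."""
    return [sid for sid, lab in zip(matrix.snp_ids, labels) if lab == OUTLIER]


def scan_epsilon(
    matrix: CodeMatrix,
    eps_grid: Sequence[float],
    downstream_eval: Callable[[list[str]], float],
    min_pts: int = 2,
) -> tuple[float, np.ndarray]:
    """Choose eps by downstream 26-class accuracy; ties go to the smaller eps.

    ``downstream_eval`` maps an outlier SNP-id list to an accuracy in
    percent.  Grids where no eps yields at least one outlier are an error.
    """
    if len(eps_grid) == 0:
        raise ValueError("eps_grid must be non-empty")
    best: tuple[float, float, np.ndarray] | None = None
    any_outliers = False
    for eps in sorted(eps_grid):
        labels = dbscan(matrix, eps=eps, min_pts=min_pts)
        outliers = select_outliers(matrix, labels)
        if not outliers:
            continue
        any_outliers = True
        acc = downstream_eval(outliers)
        if best is None or acc > best[0]:
            best = (acc, eps, labels)
    if not any_outliers:
        raise ValueError("no eps in the grid produced any outlier SNP")
    assert best is not None
    return best[1], best[2]
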