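"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written in a different style from the
library code (explicit loops, set-based bookkeeping) so that agreement is
meaningful.
"""

from __future__ import annotations

import math

import numpy as np


# -- density clustering ------------------------------------------------------

def brute_force_dbscan(X: np.ndarray, eps: float, min_pts: int) -> list[int]:
    """Classic neighbourhood-expansion DBSCAN; labels: -1 noise, clusters 1..k.

    Core points count themselves; border points join the first cluster that
    reaches them; seed points are visited in input order.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    neigh = []
    for i in range(n):
        nb = []
        for j in range(n):
            if math.dist(X[i], X[j]) <= eps:
                nb.append(j)
        neigh.append(nb)
    core = [len(nb) >= min_pts for nb in neigh]
    labels: list[int | None] = [None] * n
    cluster = 0
    for i in range(n):
        if labels[i] is not None:
            continue
        if not core[i]:
            labels[i] = -1  # may later become a border point
            continue
        cluster += 1
        # all points density-reachable from i: expand through core points only
        processed: set[int] = set()
        todo = {i}
        reach: set[int] = set()
        while todo:
            j = todo.pop()
            processed.add(j)
            for k in neigh[j]:
                reach.add(k)
                if core[k] and k not in processed:
                    todo.add(k)
        for k in reach:
            if labels[k] is None or labels[k] == -1:
                labels[k] = cluster
    return labels


def partitions_equal(labels_a, labels_b) -> bool:
    """True iff two labelings agree up to cluster relabeling (noise fixed)."""
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    if len(labels_a) != len(labels_b):
        return False
    fwd: dict = {}
    bwd: dict = {}
    for a, b in zip(labels_a, labels_b):
        if (a == -1) != (b == -1):
            return False
        if a == -1:
            continue
        if fwd.setdefault(a, b) != b or bwd.setdefault(b, a) != a:
            return False
    return True


# -- greedy correlation pruning ---------------------------------------------

def reference_panel_scan(perf_values: np.ndarray, snp_ids: list[str],
                         ranking_col: int, threshold: float) -> list[str]:
    """Step-by-step greedy scan using per-pair Pearson on continent elements."""
    order = sorted(range(len(snp_ids)),
                   key=lambda i: (-perf_values[i, ranking_col], i))
    kept: list[int] = []
    for i in order:
        ok = True
        for j in kept:
            c = pearson_continents(perf_values[i], perf_values[j])
            if c is not None and c > threshold:
                ok = False
                break
        if ok:
            kept.append(i)
    return [snp_ids[i] for i in kept]


def pearson_continents(x_i, x_k):
    """Pearson over elements 1..5; None when undefined."""
    a = [float(v) for v in x_i[1:6]]
    b = [float(v) for v in x_k[1:6]]
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    num = sum((u - ma) * (v - mb) for u, v in zip(a, b))
    da = math.sqrt(sum((u - ma) ** 2 for u in a))
    db = math.sqrt(sum((v - mb) ** 2 for v in b))
    if da == 0 or db == 0:
        return None
    return num / (da * db)


# -- cleaning rules ----------------------------------------------------------

def record_survives_cleaning(record) -> bool:
    """Per-rule brute-force checker for the three cleaning rules."""
    if len(record.ref) > 1:
        return False
    for alt in record.alts:
        if record.ref in alt:
            return False
    if all(gt == (record.ref, record.ref) for gt in record.genotypes):
        return False
    return True
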