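"""Stage 3: correlation-based redundancy pruning of candidate SNPs.

Two SNPs are redundant when the Pearson correlation of their five-continent
performance profiles exceeds a threshold ``th``; the better-ranked SNP is
kept.  Candidates are ranked by overall 26-class accuracy (continental
panels) or by a single continent's column (pairwise sub-population panels)
and scanned greedily: a SNP joins the panel iff its correlation with every
SNP already kept is at most ``th``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .performance import PerformanceMatrix, panel_accuracy


def continent_correlation(x_i: np.ndarray, x_k: np.ndarray) -> float:
    """Pearson correlation over the five continent elements (indices 1..5).

    Returns NaN (undefined) when either profile is constant across the
    continents.
    """
    a = np.asarray(x_i, dtype=float)[1:]
    b = np.asarray(x_k, dtype=float)[1:]
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da * da).sum()) * np.sqrt((db * db).sum())
    if denom == 0.0:
        return float("nan")
    return float((da * db).sum() / denom)


@dataclass
class SelectionConfig:
    threshold: float
    ranking: str = "overall"  # "overall" or a continent name

    def __post_init__(self) -> None:
        if not -1.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [-1, 1]")


@dataclass
class SnpPanel:
    """A non-redundant SNP panel, in retention (rank) order."""

    snp_ids: list[str]
    threshold: float
    ranking: str
    accuracy: float | None = field(default=None)

    def __len__(self) -> int:
        return len(self.snp_ids)


class CorrelationPruner(BaseEstimator):
    """Greedy forward selection of SNPs with non-redundant continent profiles.

    Fit on a performance matrix (rows in genomic order).  SNPs are sorted
    descending by the ranking column — ties keep genomic (input) order —
    and scanned in rank order; a SNP is kept iff its continent-profile
    correlation with *every* previously kept SNP is <= ``threshold``.
    Undefined correlations (a constant profile) never trigger pruning.

    Attributes
    ----------
    selected_ids_ : kept SNP ids in retention order.
    support_ : boolean mask over the input rows.
    order_ : rank order used for the scan (indices into the input rows).
    """

    def __init__(self, threshold: float = 0.91, ranking: str = "overall"):
        self.threshold = threshold
        self.ranking = ranking

    def fit(self, perf: PerformanceMatrix, y=None) -> "CorrelationPruner":
        SelectionConfig(self.threshold, self.ranking)  # validates
        if len(perf.snp_ids) == 0:
            raise ValueError("performance matrix is empty")
        if self.ranking == "overall":
            key = perf.values[:, 0]
        else:
            try:
                key = perf.values[:, perf.columns.index(self.ranking)]
            except ValueError:
                raise ValueError(f"unknown ranking column {self.ranking!r}")
        order = np.argsort(-key, kind="stable")  # stable: ties keep genomic order

        # centred, normalised continent profiles; zero vector when constant
        prof = perf.values[:, 1:].astype(float)
        prof = prof - prof.mean(axis=1, keepdims=True)
        norms = np.sqrt((prof * prof).sum(axis=1))
        defined = norms > 0
        unit = np.where(defined[:, None], prof / np.where(norms == 0, 1, norms)[:, None], 0.0)

        kept: list[int] = []
        kept_units: list[np.ndarray] = []
        kept_defined: list[bool] = []
        for idx in order:
            redundant = False
            if defined[idx]:
                for u, d in zip(kept_units, kept_defined):
                    if d and float(unit[idx] @ u) > self.threshold:
                        redundant = True
                        break
            if not redundant:
                kept.append(int(idx))
                kept_units.append(unit[idx])
                kept_defined.append(bool(defined[idx]))
        self.order_ = order
        self.selected_ids_ = [perf.snp_ids[i] for i in kept]
        self.support_ = np.zeros(len(perf.snp_ids), dtype=bool)
        self.support_[kept] = True
        return self


def greedy_nonredundant(perf: PerformanceMatrix, config: SelectionConfig) -> SnpPanel:
    pruner = CorrelationPruner(threshold=config.threshold, ranking=config.ranking).fit(perf)
    return SnpPanel(
        snp_ids=pruner.selected_ids_, threshold=config.threshold, ranking=config.ranking
    )


def pairwise_panel(
    perf: PerformanceMatrix,
    meta: pd.DataFrame,
    continent_j: str,
    s1: str,
    s2: str,
    th: float,
) -> SnpPanel:
    """Panel for binary classification of sub-populations s1, s2 of a continent."""
    pops = meta.loc[meta["continent"] == continent_j, "population"].unique()
    for s in (s1, s2):
        if s not in pops:
            raise ValueError(f"{s} is not a sub-population of {continent_j}")
    return greedy_nonredundant(perf, SelectionConfig(threshold=th, ranking=continent_j))


def scan_thresholds(
    perf: PerformanceMatrix,
    features: pd.DataFrame,
    meta: pd.DataFrame,
    split: tuple[list[str], list[str]],
    th_grid: Sequence[float] | None = None,
    task: str = "continental",
    pops: tuple[str, str] | None = None,
    continent: str | None = None,
    size_cap: int = 206,
    clf_params: dict | None = None,
) -> tuple[pd.DataFrame, SnpPanel]:
    """Panel size and test accuracy across a grid of correlation thresholds.

    Returns the (threshold, panel_size, accuracy) table and the best small
    panel: highest accuracy among panels of at most ``size_cap`` SNPs, ties
    to the smaller panel and then the smaller threshold.
    """
    if th_grid is None:
        th_grid = default_threshold_grid()
    if len(th_grid) == 0:
        raise ValueError("threshold grid is empty")
    ranking = "overall" if task in ("continental", "26pop") else continent
    if task == "pairwise" and (ranking is None or pops is None):
        raise ValueError("pairwise scan requires continent and pops")
    rows = []
    best: tuple[float, int, float, SnpPanel] | None = None
    for th in th_grid:
        panel = greedy_nonredundant(perf, SelectionConfig(threshold=th, ranking=ranking))
        acc = panel_accuracy(
            panel.snp_ids, features, meta, split, task=task, pops=pops, clf_params=clf_params
        )
        panel.accuracy = acc
        rows.append({"threshold": th, "panel_size": len(panel), "accuracy": acc})
        if len(panel) <= size_cap:
            cand = (acc, -len(panel), -th, panel)
            if best is None or (cand[0], cand[1], cand[2]) > (best[0], best[1], best[2]):
                best = cand
    table = pd.DataFrame(rows)
    if best is None:
        raise ValueError(f"no threshold produced a panel of <= {size_cap} SNPs")
    return table, best[3]


def default_threshold_grid() -> np.ndarray:
    """The standard scan grid: 0.10 to 0.99 in steps of 0.01."""
    return np.round(np.arange(0.10, 0.995, 0.01), 2)
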