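"""Single-SNP classification performance and the m x 6 performance matrix.

Each candidate SNP is scored as a stand-alone 26-class ancestry classifier
using its allele-context feature (0, 1 or 2 nucleotides differing from the
reference).  A SNP's row of the performance matrix X is

    [overall 26-class test accuracy %, per-continent correct %  (5 values)]

where a test individual from continent j counts as continent-correct iff
the continent of the predicted population equals j.  The five continent
elements are the profile later used for correlation-based redundancy
pruning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import VariantRecord, logger, population_to_continent
from .softmax import SoftmaxClassifier

#: canonical continent ordering for performance-matrix columns
CONTINENT_ORDER = ["Europe", "America", "Africa", "East Asia", "South Asia"]


def allele_context(record: VariantRecord, sample_index: int) -> int:
    """Number of the sample's two nucleotides differing from the reference."""
    a, b = record.genotypes[sample_index]
    return int(a != record.ref) + int(b != record.ref)


def allele_context_matrix(
    records: Sequence[VariantRecord], sample_ids: list[str]
) -> pd.DataFrame:
    """Samples x SNPs matrix of allele-context features (entries in {0,1,2})."""
    values = np.empty((len(sample_ids), len(records)), dtype=np.int8)
    for j, rec in enumerate(records):
        ref = rec.ref
        values[:, j] = [int(a != ref) + int(b != ref) for a, b in rec.genotypes]
    return pd.DataFrame(values, index=list(sample_ids), columns=[r.rsid for r in records])


def make_split(
    meta: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Population-stratified train/test split, deterministic given the seed.

    Within each population the train count is floor(n * fraction); the
    remainder goes to test, so every population appears in both sets.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for pop, group in meta.groupby("population", sort=True):
        ids = group["sample_id"].tolist()
        if len(ids) < 2:
            raise ValueError(f"population {pop} has fewer than 2 samples")
        order = rng.permutation(len(ids))
        n_train = int(np.floor(len(ids) * train_fraction))
        n_train = min(max(n_train, 1), len(ids) - 1)  # both sides non-empty
        train.extend(ids[i] for i in order[:n_train])
        test.extend(ids[i] for i in order[n_train:])
    return sorted(train), sorted(test)


def continent_columns(meta: pd.DataFrame) -> list[str]:
    """Continents present, in canonical order (extras appended sorted)."""
    present = set(meta["continent"])
    cols = [c for c in CONTINENT_ORDER if c in present]
    cols += sorted(present - set(CONTINENT_ORDER))
    return cols


@dataclass
class PerformanceMatrix:
    """Rows = SNPs; columns = [overall, <continents...>], percentages."""

    snp_ids: list[str]
    values: np.ndarray  # (m, 1 + n_continents)
    columns: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.snp_ids, columns=self.columns)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PerformanceMatrix":
        return cls(
            snp_ids=list(df.index), values=df.to_numpy(float), columns=list(df.columns)
        )


def _fit_single_feature(
    x_train: np.ndarray, y_train: np.ndarray, clf_params: dict
) -> SoftmaxClassifier:
    """Fit the shared softmax trainer on one feature.

    Full-batch gradient descent depends on the data only through the counts
    of (feature value, label) pairs, so the fit runs on the unique pairs with
    their multiplicities as sample weights — exactly equal to the naive fit.
    """
    pairs = np.stack([x_train, y_train], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    clf = SoftmaxClassifier(**clf_params)
    clf.fit(uniq[:, [0]].astype(float), uniq[:, 1], sample_weight=counts)
    return clf


def build_performance_matrix(
    candidate_snps: Sequence[str],
    features: pd.DataFrame,
    meta: pd.DataFrame,
    split: tuple[list[str], list[str]],
    clf_params: dict | None = None,
) -> PerformanceMatrix:
    """Score every candidate SNP independently as a 26-class classifier.

    ``features`` is the samples x SNPs allele-context matrix; each SNP is
    trained and evaluated on its own column only.
    """
    clf_params = clf_params or {}
    train_ids, test_ids = split
    pop_of = dict(zip(meta["sample_id"], meta["population"]))
    cont_of = population_to_continent(meta)
    conts = continent_columns(meta)

    y_train = np.array([pop_of[s] for s in train_ids])
    y_test_pop = np.array([pop_of[s] for s in test_ids])
    test_cont = np.array([cont_of[p] for p in y_test_pop])

    rows = np.empty((len(candidate_snps), 1 + len(conts)))
    n_constant = 0
    for i, snp in enumerate(candidate_snps):
        x_train = features.loc[train_ids, snp].to_numpy()
        x_test = features.loc[test_ids, snp].to_numpy()
        if x_train.min() == x_train.max():
            n_constant += 1
        clf = _fit_single_feature(x_train, y_train, clf_params)
        # feature takes at most 3 values: predict each once, then map
        values = np.unique(np.concatenate([x_train, x_test]))
        pred_of = dict(zip(values, clf.predict(values[:, None].astype(float))))
        pred = np.array([pred_of[v] for v in x_test])
        rows[i, 0] = 100.0 * float((pred == y_test_pop).mean())
        pred_cont = np.array([cont_of[p] for p in pred])
        for j, cont in enumerate(conts, start=1):
            sel = test_cont == cont
            rows[i, j] = 100.0 * float((pred_cont[sel] == cont).mean())
    if n_constant:
        logger.info(
            "build_performance_matrix: %d candidate SNP(s) constant on the "
            "training set (scored as constant classifiers)",
            n_constant,
        )
    return PerformanceMatrix(
        snp_ids=list(candidate_snps), values=rows, columns=["overall", *conts]
    )


def panel_accuracy(
    panel: Sequence[str],
    features: pd.DataFrame,
    meta: pd.DataFrame,
    split: tuple[list[str], list[str]],
    task: str = "continental",
    pops: tuple[str, str] | None = None,
    clf_params: dict | None = None,
) -> float:
    """Train the softmax classifier on a SNP panel and return test accuracy %.

    ``task`` is ``"continental"`` (5-class over all samples), ``"26pop"``
    (population-level) or ``"pairwise"`` (binary between ``pops``, samples
    restricted to those two populations).
    """
    clf_params = clf_params or {}
    train_ids, test_ids = split
    pop_of = dict(zip(meta["sample_id"], meta["population"]))
    cont_of = population_to_continent(meta)

    if task == "pairwise":
        if pops is None:
            raise ValueError("pairwise task requires pops=(S1, S2)")
        keep = set(meta.loc[meta["population"].isin(pops), "sample_id"])
        train_ids = [s for s in train_ids if s in keep]
        test_ids = [s for s in test_ids if s in keep]
        label_of = pop_of
    elif task == "26pop":
        label_of = pop_of
    elif task == "continental":
        label_of = {s: cont_of[pop_of[s]] for s in meta["sample_id"]}
    else:
        raise ValueError(f"unknown task {task!r}")

    X_train = features.loc[train_ids, list(panel)].to_numpy(float)
    X_test = features.loc[test_ids, list(panel)].to_numpy(float)
    y_train = np.array([label_of[s] for s in train_ids])
    y_test = np.array([label_of[s] for s in test_ids])
    clf = SoftmaxClassifier(**clf_params).fit(X_train, y_train)
    return 100.0 * float((clf.predict(X_test) == y_test).mean())
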