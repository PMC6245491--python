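"""Allele-context features, the stratified split, and the performance matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chromaim import VariantRecord, allele_context, allele_context_matrix, make_split
from chromaim.performance import build_performance_matrix
from chromaim.softmax import SoftmaxClassifier

#: published study design: population -> sample size (26 populations)
STUDY_SIZES = {
    "PUR": 104, "CLM": 94, "PEL": 85, "MXL": 64,
    "GBR": 91, "FIN": 99, "IBS": 107, "CEU": 99, "TSI": 107,
    "CHS": 105, "CDX": 93, "KHV": 99, "CHB": 103, "JPT": 104,
    "PJL": 96, "BEB": 86, "STU": 102, "ITU": 102, "GIH": 103,
    "ACB": 96, "GWD": 113, "ESN": 99, "MSL": 85, "YRI": 108,
    "LWK": 99, "ASW": 61,
}


@pytest.mark.parametrize(
    "genotype,expected",
    [(("A", "A"), 0), (("A", "G"), 1), (("G", "A"), 1), (("G", "T"), 2)],
)
def test_allele_context_counts_non_reference_nucleotides(genotype, expected):
    rec = VariantRecord("rs1", "1", 1, "A", ["G", "T"], [genotype])
    assert allele_context(rec, 0) == expected


def test_allele_context_matrix_shape_and_values():
    recs = [
        VariantRecord("rs1", "1", 1, "A", ["G"], [("A", "A"), ("A", "G")]),
        VariantRecord("rs2", "1", 2, "C", ["T"], [("T", "T"), ("C", "T")]),
    ]
    m = allele_context_matrix(recs, ["s1", "s2"])
    assert m.values.tolist() == [[0, 2], [1, 1]]
    assert list(m.columns) == ["rs1", "rs2"]


def _uniform_meta(n_per_pop=10, n_pops=26):
    rows = [
        (f"P{p:02d}_{k}", f"P{p:02d}", f"C{p % 5}")
        for p in range(n_pops)
        for k in range(n_per_pop)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "population", "continent"])


def test_split_stratification_arithmetic():
    meta = _uniform_meta()
    train, test = make_split(meta, 0.8, seed=0)
    assert len(train) == 26 * 8 and len(test) == 26 * 2
    pops_train = meta.set_index("sample_id").loc[train, "population"]
    assert (pops_train.value_counts() == 8).all()
    assert sorted(train + test) == sorted(meta["sample_id"])


def test_split_deterministic_and_seed_sensitive():
    meta = _uniform_meta()
    assert make_split(meta, 0.8, seed=5) == make_split(meta, 0.8, seed=5)
    assert make_split(meta, 0.8, seed=5) != make_split(meta, 0.8, seed=6)


def test_split_study_design_sizes_floor_rule():
    """80/20 on the 26-population study sizes: per-stratum floor rounding."""
    rows = [
        (f"{pop}_{k}", pop, "X") for pop, n in STUDY_SIZES.items() for k in range(n)
    ]
    meta = pd.DataFrame(rows, columns=["sample_id", "population", "continent"])
    train, test = make_split(meta, 0.8, seed=0)
    expected_train = sum(int(np.floor(0.8 * n)) for n in STUDY_SIZES.values())
    assert len(train) == expected_train
    assert len(train) + len(test) == sum(STUDY_SIZES.values()) == 2504


def test_split_rejects_tiny_population():
    meta = pd.DataFrame(
        [("s1", "P1", "X"), ("s2", "P2", "X"), ("s3", "P2", "X")],
        columns=["sample_id", "population", "continent"],
    )
    with pytest.raises(ValueError, match="fewer than 2"):
        make_split(meta, 0.8, 0)


def _toy_setup():
    """3 populations over 2 continents, 6 samples each, hand-made features."""
    rows = []
    for pop, cont in [("P1", "Europe"), ("P2", "Europe"), ("P3", "Africa")]:
        for k in range(6):
            rows.append((f"{pop}_{k}", pop, cont))
    meta = pd.DataFrame(rows, columns=["sample_id", "population", "continent"])
    samples = meta["sample_id"].tolist()
    split = make_split(meta, 0.8, seed=0)
    return meta, samples, split


def test_perfectly_separating_snp_scores_100_for_its_continent():
    meta, samples, split = _toy_setup()
    # feature 2 exactly for Africa samples, 0 elsewhere
    feat = pd.DataFrame(
        {"snp_af": [2 if s.startswith("P3") else 0 for s in samples]}, index=samples
    )
    perf = build_performance_matrix(["snp_af"], feat, meta, split)
    africa_col = perf.columns.index("Africa")
    assert perf.values[0, africa_col] == 100.0


def test_constant_snp_scores_majority_class_rate():
    meta, samples, split = _toy_setup()
    feat = pd.DataFrame({"snp_const": [1] * len(samples)}, index=samples)
    perf = build_performance_matrix(["snp_const"], feat, meta, split)
    _, test_ids = split
    pops = meta.set_index("sample_id").loc[test_ids, "population"]
    majority_rate = 100.0 * pops.value_counts(sort=True).iloc[0] / len(test_ids)
    assert perf.values[0, 0] == pytest.approx(majority_rate)


def test_rows_in_percent_range_and_deterministic(small_sim):
    _, sample_ids, records, meta, _ = small_sim
    split = make_split(meta, 0.8, seed=0)
    feat = allele_context_matrix(list(records[:30]), sample_ids)
    snps = list(feat.columns)
    a = build_performance_matrix(snps, feat, meta, split)
    b = build_performance_matrix(snps, feat, meta, split)
    assert np.array_equal(a.values, b.values)
    assert (a.values >= 0).all() and (a.values <= 100).all()
    assert a.columns[0] == "overall" and len(a.columns) == 6


def test_row_depends_only_on_own_feature_column(small_sim):
    _, sample_ids, records, meta, _ = small_sim
    split = make_split(meta, 0.8, seed=0)
    feat = allele_context_matrix(list(records[:10]), sample_ids)
    target = feat.columns[0]
    a = build_performance_matrix([target], feat, meta, split)
    shuffled = feat.copy()
    rng = np.random.default_rng(1)
    for col in feat.columns[1:]:
        shuffled[col] = rng.permutation(shuffled[col].to_numpy())
    b = build_performance_matrix([target], shuffled, meta, split)
    assert np.array_equal(a.values, b.values)


def test_matrix_equals_naive_per_snp_reimplementation(small_sim):
    """The weighted unique-pair fit equals a plain per-sample softmax fit."""
    _, sample_ids, records, meta, _ = small_sim
    split = make_split(meta, 0.8, seed=0)
    train_ids, test_ids = split
    feat = allele_context_matrix(list(records[:15]), sample_ids)
    perf = build_performance_matrix(list(feat.columns), feat, meta, split)

    pop_of = dict(zip(meta["sample_id"], meta["population"]))
    cont_of = dict(zip(meta["population"], meta["continent"]))
    y_train = np.array([pop_of[s] for s in train_ids])
    y_test = np.array([pop_of[s] for s in test_ids])
    for i, snp in enumerate(feat.columns):
        clf = SoftmaxClassifier().fit(
            feat.loc[train_ids, snp].to_numpy(float)[:, None], y_train
        )
        pred = clf.predict(feat.loc[test_ids, snp].to_numpy(float)[:, None])
        assert perf.values[i, 0] == pytest.approx(100.0 * (pred == y_test).mean())
        for j, cont in enumerate(perf.columns[1:], start=1):
            sel = np.array([cont_of[p] == cont for p in y_test])
            got = 100.0 * np.mean([cont_of[p] == cont for p in pred[sel]])
            assert perf.values[i, j] == pytest.approx(got)


def test_overall_equals_population_weighted_mean(small_sim):
    """Column 1 is the test-count-weighted mean of per-population accuracy."""
    _, sample_ids, records, meta, _ = small_sim
    split = make_split(meta, 0.8, seed=0)
    train_ids, test_ids = split
    feat = allele_context_matrix(list(records[:8]), sample_ids)
    perf = build_performance_matrix(list(feat.columns), feat, meta, split)
    pop_of = dict(zip(meta["sample_id"], meta["population"]))
    y_test = np.array([pop_of[s] for s in test_ids])
    y_train = np.array([pop_of[s] for s in train_ids])
    for i, snp in enumerate(feat.columns):
        clf = SoftmaxClassifier().fit(
            feat.loc[train_ids, snp].to_numpy(float)[:, None], y_train
        )
        pred = clf.predict(feat.loc[test_ids, snp].to_numpy(float)[:, None])
        acc_by_pop = {
            pop: 100.0 * np.mean(pred[y_test == pop] == pop) for pop in set(y_test)
        }
        weighted = sum(
            acc_by_pop[pop] * (y_test == pop).sum() for pop in acc_by_pop
        ) / len(y_test)
        assert perf.values[i, 0] == pytest.approx(weighted)
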