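"""Stage 1: parameter-based SNP selection.

For each (SNP, population) pair over the *training* individuals we compute

    alpha = n_p^i / n_p        (fraction of population p retained at SNP i)
    beta  = f_p^i / n_p^i      (fraction carrying the modal genotype symbol)

A SNP is diagnostic for population p when alpha * beta = 1, i.e. every
training member of p is retained and they all share one genotype symbol.
The stage keeps the union of the per-population diagnostic sets, then drops
SNPs whose retained training individuals (pooled over all populations) share
a single symbol — such sites cannot separate populations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .preprocess import MaskedVariant


@dataclass
class PopulationSnpStats:
    snp_id: str
    population: str
    n_p: int
    n_p_i: int
    f_p_i: int
    alpha: float
    beta: float | None  # None when n_p_i == 0

    @property
    def diagnostic(self) -> bool:
        return self.alpha == 1.0 and self.beta == 1.0


def _training_symbols(
    mv: MaskedVariant, sample_ids: list[str], training: set[str]
) -> list[tuple[str, tuple[str, str]]]:
    """(sample_id, symbol) for retained training samples at this SNP."""
    out = []
    for sid, keep, gt in zip(sample_ids, mv.retained, mv.record.genotypes):
        if keep and sid in training:
            out.append((sid, gt))
    return out


def compute_alpha_beta(
    mv: MaskedVariant,
    sample_ids: list[str],
    meta: pd.DataFrame,
    training_ids: list[str],
) -> list[PopulationSnpStats]:
    """Per-population alpha/beta statistics over the training split."""
    training = set(training_ids)
    pop_of = dict(zip(meta["sample_id"], meta["population"]))
    populations = sorted(set(meta["population"]))
    n_p = Counter(pop_of[s] for s in training_ids)
    if not n_p:
        raise ValueError("no training individuals")
    sym_by_pop: dict[str, Counter] = {p: Counter() for p in populations}
    for sid, gt in _training_symbols(mv, sample_ids, training):
        sym_by_pop[pop_of[sid]][gt] += 1
    stats = []
    for pop in populations:
        if n_p[pop] == 0:
            raise ValueError(f"population {pop} has no training individuals")
        counts = sym_by_pop[pop]
        n_p_i = sum(counts.values())
        f_p_i = max(counts.values()) if counts else 0
        stats.append(
            PopulationSnpStats(
                snp_id=mv.rsid,
                population=pop,
                n_p=n_p[pop],
                n_p_i=n_p_i,
                f_p_i=f_p_i,
                alpha=n_p_i / n_p[pop],
                beta=(f_p_i / n_p_i) if n_p_i else None,
            )
        )
    return stats


def select_important(
    dissimilarity: list[MaskedVariant],
    sample_ids: list[str],
    meta: pd.DataFrame,
    training_ids: list[str],
) -> set[str]:
    """Union over populations of SNPs with alpha = beta = 1 for that population."""
    selected: set[str] = set()
    for mv in dissimilarity:
        for st in compute_alpha_beta(mv, sample_ids, meta, training_ids):
            if st.diagnostic:
                selected.add(mv.rsid)
                break
    return selected


def drop_uniform(
    selected: set[str],
    dissimilarity: list[MaskedVariant],
    sample_ids: list[str],
    training_ids: list[str],
) -> set[str]:
    """Remove selected SNPs uniform across all retained training individuals."""
    training = set(training_ids)
    kept: set[str] = set()
    for mv in dissimilarity:
        if mv.rsid not in selected:
            continue
        symbols = {gt for _, gt in _training_symbols(mv, sample_ids, training)}
        if len(symbols) > 1:
            kept.add(mv.rsid)
    return kept


def stage1_select(
    dissimilarity: list[MaskedVariant],
    sample_ids: list[str],
    meta: pd.DataFrame,
    training_ids: list[str],
) -> set[str]:
    """Full Stage 1: diagnostic-union selection followed by uniform removal."""
    selected = select_important(dissimilarity, sample_ids, meta, training_ids)
    return drop_uniform(selected, dissimilarity, sample_ids, training_ids)
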