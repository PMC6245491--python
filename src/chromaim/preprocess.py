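"""Site-level cleaning, reference-homozygote masking and the
similarity/dissimilarity partition.

Cleaning applies three rules, in order:

1. drop sites whose reference allele has more than one nucleotide;
2. drop sites where an alternate allele contains the reference nucleotide;
3. drop sites where every individual is homozygous for the reference.

After cleaning, each individual whose two nucleotides both equal the
reference is *masked* at that site (their allele information carries no
signal beyond the reference).  A site whose retained individuals all share
one ordered genotype symbol goes to the *similarity* set; everything else is
the *dissimilarity* set, the only input to panel selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import VariantRecord, logger


@dataclass
class MaskedVariant:
    """A cleaned variant plus the per-sample retention mask.

    ``retained[s]`` is False iff sample ``s`` is homozygous-reference here;
    ``symbols`` holds the ordered genotype pair of each *retained* sample, in
    sample order.
    """

    record: VariantRecord
    retained: np.ndarray  # bool, one per sample
    symbols: list[tuple[str, str]]

    @property
    def rsid(self) -> str:
        return self.record.rsid


def clean_variants(
    records: list[VariantRecord],
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the three cleaning rules; returns survivors and per-rule counts."""
    kept: list[VariantRecord] = []
    removed = {"rule1_multibase_ref": 0, "rule2_alt_contains_ref": 0, "rule3_all_hom_ref": 0}
    for rec in records:
        if len(rec.ref) > 1:
            removed["rule1_multibase_ref"] += 1
            continue
        if any(rec.ref in alt for alt in rec.alts):
            removed["rule2_alt_contains_ref"] += 1
            continue
        if all(a == rec.ref and b == rec.ref for a, b in rec.genotypes):
            removed["rule3_all_hom_ref"] += 1
            continue
        kept.append(rec)
    if any(removed.values()):
        logger.info("clean_variants: removed %s", removed)
    return kept, removed


def mask_reference_homozygotes(record: VariantRecord) -> MaskedVariant:
    """Mask individuals whose two nucleotides both equal the reference."""
    retained = np.array(
        [not (a == record.ref and b == record.ref) for a, b in record.genotypes],
        dtype=bool,
    )
    symbols = [gt for gt, keep in zip(record.genotypes, retained) if keep]
    return MaskedVariant(record=record, retained=retained, symbols=symbols)


def partition_similarity(
    masked: list[MaskedVariant],
) -> tuple[list[MaskedVariant], list[MaskedVariant]]:
    """Split masked variants into (similarity_set, dissimilarity_set)."""
    similarity: list[MaskedVariant] = []
    dissimilarity: list[MaskedVariant] = []
    for mv in masked:
        if len(set(mv.symbols)) == 1:
            similarity.append(mv)
        else:
            dissimilarity.append(mv)
    return similarity, dissimilarity


def preprocess(
    records: list[VariantRecord],
) -> tuple[list[MaskedVariant], dict[str, int]]:
    """Clean, mask and keep only the dissimilarity set (the panel input)."""
    kept, removed = clean_variants(records)
    masked = [mask_reference_homozygotes(r) for r in kept]
    similarity, dissimilarity = partition_similarity(masked)
    counts = dict(removed)
    counts["similarity_set"] = len(similarity)
    counts["dissimilarity_set"] = len(dissimilarity)
    return dissimilarity, counts
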