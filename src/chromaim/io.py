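"""Variant and sample-metadata I/O.

Genotypes are exposed as ordered nucleotide pairs (the maternal/paternal
order of the GT field is preserved), decoupled from VCF syntax.  Reading is
backed by cyvcf2; writing emits minimal, byte-deterministic VCF v4.2 text so
that pipeline reruns are bit-identical.
"""

from __future__ import annotations

import gzip
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("chromaim")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("chromaim: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

NUCLEOTIDES = frozenset("ACGT")


@dataclass
class VariantRecord:
    """One SNP site with per-sample diploid genotypes.

    ``genotypes[s]`` is the ordered nucleotide pair of sample ``s`` (order as
    read from the GT field; phased and unphased separators are equivalent).
    """

    rsid: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: list[str] = field(default_factory=list)
    genotypes: list[tuple[str, str]] = field(default_factory=list)

    def validate(self, n_samples: int | None = None) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: pos must be >= 1, got {self.pos}")
        for allele in [self.ref, *self.alts]:
            if not allele or not set(allele) <= NUCLEOTIDES:
                raise ValueError(f"{self.rsid}: bad allele {allele!r}")
        if n_samples is not None and len(self.genotypes) != n_samples:
            raise ValueError(
                f"{self.rsid}: {len(self.genotypes)} genotypes for {n_samples} samples"
            )
        for gt in self.genotypes:
            if len(gt) != 2 or any(n not in NUCLEOTIDES for n in gt):
                raise ValueError(f"{self.rsid}: bad genotype {gt!r}")


class VcfParseError(ValueError):
    pass


def read_vcf(path: str | Path) -> tuple[list[str], list[VariantRecord]]:
    """Read a (possibly gzipped) VCF into sample IDs and variant records.

    Records with any missing genotype (``./.``) are dropped with a logged
    count, since every downstream statistic assumes complete diploid data.
    Records whose REF or any ALT is longer than one base (indels) are dropped
    likewise; site-level cleaning handles the remaining rules.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    records: list[VariantRecord] = []
    n_missing = 0
    n_indel = 0
    for line_no, var in enumerate(vcf, start=1):
        alleles = [var.REF] + list(var.ALT)
        if any(len(a) != 1 for a in alleles):
            n_indel += 1
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...] in GT-field order
        pairs: list[tuple[str, str]] = []
        missing = False
        for g in gts:
            a0, a1 = int(g[0]), int(g[1])
            if a0 < 0 or a1 < 0:
                missing = True
                break
            if a0 >= len(alleles) or a1 >= len(alleles):
                raise VcfParseError(
                    f"{path}: record {line_no} ({var.ID}): GT index beyond ALT list"
                )
            pairs.append((alleles[a0], alleles[a1]))
        if missing:
            n_missing += 1
            continue
        records.append(
            VariantRecord(
                rsid=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alts=list(var.ALT),
                genotypes=pairs,
            )
        )
    if n_missing or n_indel:
        logger.info(
            "read_vcf: dropped %d records with missing genotypes, %d indel records",
            n_missing,
            n_indel,
        )
    return sample_ids, records


def _gt_field(record: VariantRecord, pair: tuple[str, str]) -> str:
    alleles = [record.ref, *record.alts]
    try:
        return f"{alleles.index(pair[0])}/{alleles.index(pair[1])}"
    except ValueError as exc:
        raise ValueError(
            f"{record.rsid}: genotype {pair} not representable by REF/ALT {alleles}"
        ) from exc


def write_vcf(
    sample_ids: Sequence[str],
    records: Sequence[VariantRecord],
    path: str | Path,
) -> Path:
    """Write minimal VCF v4.2; inverse of :func:`read_vcf` on valid inputs.

    ``.gz`` paths are gzip-compressed with a zeroed mtime so identical inputs
    produce identical bytes.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    for chrom in dict.fromkeys(r.chrom for r in records):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids)
    )
    for rec in records:
        rec.validate(n_samples=len(sample_ids))
        gt_fields = [_gt_field(rec, pair) for pair in rec.genotypes]
        lines.append(
            "\t".join(
                [
                    rec.chrom,
                    str(rec.pos),
                    rec.rsid,
                    rec.ref,
                    ",".join(rec.alts) if rec.alts else ".",
                    ".",
                    ".",
                    ".",
                    "GT",
                    *gt_fields,
                ]
            )
        )
    payload = ("\n".join(lines) + "\n").encode()
    if path.suffix == ".gz":
        with open(path, "wb") as fh:
            with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(payload)
    else:
        path.write_bytes(payload)
    return path


METADATA_COLUMNS = ("sample_id", "population", "continent")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, population, continent).

    Enforces that the population -> continent mapping is a function and that
    sample IDs are unique.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    unknown = set(meta.columns) - set(METADATA_COLUMNS)
    if unknown or set(METADATA_COLUMNS) - set(meta.columns):
        raise ValueError(
            f"metadata columns must be {METADATA_COLUMNS}, got {tuple(meta.columns)}"
        )
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s): {dupes}")
    n_continents = meta.groupby("population")["continent"].nunique()
    bad = n_continents[n_continents > 1].index.tolist()
    if bad:
        raise ValueError(f"population(s) mapped to multiple continents: {bad}")
    return meta.reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    meta.loc[:, list(METADATA_COLUMNS)].to_csv(path, sep="\t", index=False)
    return path


def population_to_continent(meta: pd.DataFrame) -> dict[str, str]:
    return dict(zip(meta["population"], meta["continent"]))
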