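"""Hierarchical structured-population genotype simulator with planted AIMs.

The generator emulates a 26-population / 5-continent sampling design
(population codes and continental assignments follow the standard
1000-Genomes-style layout) under a two-level Balding–Nichols model:

* ancestral reference-allele frequency  p ~ Uniform(0.05, 0.95);
* continent frequency  p_c ~ Beta(p (1-Fc)/Fc, (1-p)(1-Fc)/Fc);
* sub-population frequency drawn the same way around p_c with Fs;
* each diploid genotype is two independent allele draws, stored in draw
  order.

A configurable number of ancestry-informative markers (AIMs) is planted
per population: the target population is homozygous-ALT, every *other*
population carries exactly one heterozygous (REF, ALT) sentinel individual,
and everyone else is homozygous-REF.  The sentinels keep the site in the
dissimilarity set (a perfectly fixed difference would leave only one
genotype symbol among retained individuals) while preserving the exact
alpha = beta = 1 signature for the target population.

Simulation is deterministic given the seed, down to the output bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import VariantRecord, write_metadata, write_vcf

#: population code -> continent, mirroring the 26-population study design
POPULATION_LAYOUT: dict[str, str] = {
    "PUR": "America", "CLM": "America", "PEL": "America", "MXL": "America",
    "GBR": "Europe", "FIN": "Europe", "IBS": "Europe", "CEU": "Europe",
    "TSI": "Europe",
    "CHS": "East Asia", "CDX": "East Asia", "KHV": "East Asia",
    "CHB": "East Asia", "JPT": "East Asia",
    "PJL": "South Asia", "BEB": "South Asia", "STU": "South Asia",
    "ITU": "South Asia", "GIH": "South Asia",
    "ACB": "Africa", "GWD": "Africa", "ESN": "Africa", "MSL": "Africa",
    "YRI": "Africa", "LWK": "Africa", "ASW": "Africa",
}

_NUC = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-design and divergence parameters of the generator.

    Defaults are the conditions used throughout the test suite: 26
    sub-populations over 5 continents, 20 samples each, 5,000 independent
    SNPs, continental divergence Fst 0.15 with sub-population divergence
    0.05 on top, and 2 planted AIMs per population.
    """

    populations: dict[str, str] = field(default_factory=lambda: dict(POPULATION_LAYOUT))
    samples_per_subpop: int = 20
    n_snps: int = 5000
    fst_continental: float = 0.15
    fst_subpop: float = 0.05
    n_planted_aims_per_pop: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fst_continental < 1 and 0 < self.fst_subpop < 1):
            raise ValueError("Fst parameters must lie in (0, 1)")
        if min(self.samples_per_subpop, self.n_snps) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_planted_aims_per_pop * len(self.populations) > self.n_snps:
            raise ValueError("more planted AIMs than SNPs")


@dataclass
class TruthManifest:
    """Ground truth of one simulation: planted AIMs and allele frequencies."""

    planted: list[dict]  # {"rsid", "population", "sentinels": [...]}
    ancestral_freq: dict[str, float]  # rsid -> ancestral REF frequency
    population_freq: dict[str, dict[str, float]]  # rsid -> pop -> REF frequency

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "planted": self.planted,
                    "ancestral_freq": self.ancestral_freq,
                    "population_freq": self.population_freq,
                },
                sort_keys=True,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        d = json.loads(Path(path).read_text())
        return cls(d["planted"], d["ancestral_freq"], d["population_freq"])


def _balding_nichols(rng, p: np.ndarray, fst: float) -> np.ndarray:
    ratio = (1 - fst) / fst
    return rng.beta(np.clip(p * ratio, 1e-12, None), np.clip((1 - p) * ratio, 1e-12, None))


def simulate_records(
    config: SimulationConfig,
) -> tuple[list[str], list[VariantRecord], pd.DataFrame, TruthManifest]:
    """Generate (sample_ids, records, metadata, truth) in memory."""
    rng = np.random.default_rng(config.seed)
    pops = list(config.populations)
    continents = list(dict.fromkeys(config.populations.values()))

    sample_ids: list[str] = []
    meta_rows = []
    for pop in pops:
        for k in range(config.samples_per_subpop):
            sid = f"{pop}_{k:03d}"
            sample_ids.append(sid)
            meta_rows.append((sid, pop, config.populations[pop]))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "population", "continent"])
    samples_of = {
        pop: [f"{pop}_{k:03d}" for k in range(config.samples_per_subpop)] for pop in pops
    }

    n_planted = config.n_planted_aims_per_pop * len(pops)
    planted_idx = rng.choice(config.n_snps, size=n_planted, replace=False)
    planted_target = {
        int(idx): pops[j // config.n_planted_aims_per_pop]
        for j, idx in enumerate(planted_idx)
    }

    records: list[VariantRecord] = []
    planted_info: list[dict] = []
    ancestral: dict[str, float] = {}
    pop_freq: dict[str, dict[str, float]] = {}
    n_samples = len(sample_ids)
    pos_of_sample = {s: i for i, s in enumerate(sample_ids)}

    for i in range(config.n_snps):
        rsid = f"rs{i + 1}"
        ref_i, alt_off = rng.integers(0, 4), rng.integers(1, 4)
        ref = str(_NUC[ref_i])
        alt = str(_NUC[(ref_i + alt_off) % 4])
        if i in planted_target:
            target = planted_target[i]
            genotypes = [(ref, ref)] * n_samples
            for s in samples_of[target]:
                genotypes[pos_of_sample[s]] = (alt, alt)
            sentinels = []
            for pop in pops:
                if pop == target:
                    continue
                s = samples_of[pop][int(rng.integers(config.samples_per_subpop))]
                genotypes[pos_of_sample[s]] = (ref, alt)
                sentinels.append(s)
            records.append(
                VariantRecord(rsid=rsid, chrom="1", pos=i + 1, ref=ref, alts=[alt],
                              genotypes=genotypes)
            )
            planted_info.append({"rsid": rsid, "population": target, "sentinels": sentinels})
            ancestral[rsid] = 1.0
            pop_freq[rsid] = {p: (0.0 if p == target else 1.0) for p in pops}
            continue

        p_anc = rng.uniform(0.05, 0.95)
        p_cont = _balding_nichols(
            rng, np.full(len(continents), p_anc), config.fst_continental
        )
        cont_freq = dict(zip(continents, p_cont))
        freqs = {
            pop: float(
                _balding_nichols(
                    rng, np.array([cont_freq[config.populations[pop]]]), config.fst_subpop
                )[0]
            )
            for pop in pops
        }
        genotypes = []
        for pop in pops:
            draws = rng.random((config.samples_per_subpop, 2)) < freqs[pop]
            for is_ref in draws:
                genotypes.append(
                    (ref if is_ref[0] else alt, ref if is_ref[1] else alt)
                )
        records.append(
            VariantRecord(rsid=rsid, chrom="1", pos=i + 1, ref=ref, alts=[alt],
                          genotypes=genotypes)
        )
        ancestral[rsid] = round(p_anc, 6)
        pop_freq[rsid] = {p: round(f, 6) for p, f in freqs.items()}

    manifest = TruthManifest(
        planted=planted_info, ancestral_freq=ancestral, population_freq=pop_freq
    )
    return sample_ids, records, meta, manifest


def simulate(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[Path, Path, TruthManifest]:
    """Simulate and write genotypes.vcf.gz, meta.tsv and truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sample_ids, records, meta, manifest = simulate_records(config)
    vcf_path = write_vcf(sample_ids, records, out_dir / "genotypes.vcf.gz")
    meta_path = write_metadata(meta, out_dir / "meta.tsv")
    manifest.to_json(out_dir / "truth.json")
    return vcf_path, meta_path, manifest


def estimate_fst(
    records: list[VariantRecord],
    sample_ids: list[str],
    meta: pd.DataFrame,
    grouping: str = "continent",
) -> float:
    """Multi-locus Weir–Cockerham-style Fst (ratio of averages).

    ``grouping`` is the metadata column defining the groups ("continent" or
    "population").  Returns NaN when every locus is monomorphic overall.
    """
    group_of = dict(zip(meta["sample_id"], meta[grouping]))
    groups = sorted(set(group_of.values()))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    gidx = {g: i for i, g in enumerate(groups)}
    cols = np.array([gidx[group_of[s]] for s in sample_ids])
    r = len(groups)

    a_sum = 0.0
    abc_sum = 0.0
    any_poly = False
    for rec in records:
        alt_count = np.array(
            [(a != rec.ref) + (b != rec.ref) for a, b in rec.genotypes], dtype=float
        )
        het = np.array([(a != b) for a, b in rec.genotypes], dtype=float)
        n_i = np.bincount(cols, minlength=r).astype(float)  # diploid counts
        p_i = np.bincount(cols, weights=alt_count, minlength=r) / (2 * n_i)
        h_i = np.bincount(cols, weights=het, minlength=r) / n_i
        n_bar = n_i.mean()
        p_bar = (n_i * p_i).sum() / (r * n_bar)
        if p_bar in (0.0, 1.0):
            continue
        any_poly = True
        n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        a_sum += a
        abc_sum += a + b + c
    if not any_poly or abc_sum == 0.0:
        return float("nan")
    return a_sum / abc_sum
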