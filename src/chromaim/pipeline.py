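"""End-to-end panel-construction pipeline and reporting.

Runs clean -> stage 1 (alpha/beta selection) -> stage 2 (DBSCAN outliers)
-> performance matrix -> threshold scan / panel -> classification, persisting
every intermediate artifact plus a manifest of seeds and funnel counts.
All artifacts are written deterministically: two runs with the same config
are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dbscan import dbscan, encode_symbols, scan_epsilon, select_outliers
from .io import (
    logger,
    population_to_continent,
    read_metadata,
    read_vcf,
    write_vcf,
)
from .performance import (
    PerformanceMatrix,
    allele_context_matrix,
    build_performance_matrix,
    make_split,
    panel_accuracy,
)
from .preprocess import clean_variants, mask_reference_homozygotes, partition_similarity
from .select import SelectionConfig, default_threshold_grid, greedy_nonredundant, scan_thresholds
from .softmax import SoftmaxClassifier, evaluate
from .stage1 import drop_uniform, select_important


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage, partial artifacts remain."""


@dataclass
class PipelineConfig:
    """Operating points of the full pipeline.

    Defaults follow the published operating points: 80/20 split, DBSCAN with
    min_pts=2 and eps=0.1, correlation-threshold grid 0.10..0.99 step 0.01,
    and a 206-SNP cap when choosing the best small panel.
    """

    vcf: str = ""
    metadata: str = ""
    out_dir: str = "chromaim_out"
    train_fraction: float = 0.8
    seed: int = 0
    eps: float = 0.1
    min_pts: int = 2
    eps_grid: list[float] | None = None
    th_grid: list[float] | None = None
    size_cap: int = 206
    pairwise: list[list[str]] = field(default_factory=list)  # [continent, S1, S2]
    learning_rate: float = 0.1
    epochs: int = 500
    l2: float = 1e-4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def clf_params(self) -> dict:
        return {"learning_rate": self.learning_rate, "epochs": self.epochs, "l2": self.l2}


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "out_dir"},
        "counts": {},
    }

    # -- input + cleaning --------------------------------------------------
    stage = "clean"
    try:
        sample_ids, records = read_vcf(config.vcf)
        meta = read_metadata(config.metadata)
        if set(meta["sample_id"]) != set(sample_ids):
            raise ValueError("metadata samples do not match VCF samples")
        manifest["counts"]["input"] = len(records)
        kept, removed = clean_variants(records)
        write_vcf(sample_ids, kept, out / "cleaned.vcf.gz")
        masked = [mask_reference_homozygotes(r) for r in kept]
        similarity, dissimilarity = partition_similarity(masked)
        manifest["counts"].update(
            {
                "cleaned": len(kept),
                "removed_per_rule": removed,
                "similarity_set": len(similarity),
                "dissimilarity_set": len(dissimilarity),
            }
        )

        # -- split + stage 1 ------------------------------------------------
        stage = "stage1"
        train_ids, test_ids = make_split(meta, config.train_fraction, config.seed)
        _write_json({"train": train_ids, "test": test_ids}, out / "split.json")
        selected = select_important(dissimilarity, sample_ids, meta, train_ids)
        stage1_ids = drop_uniform(selected, dissimilarity, sample_ids, train_ids)
        stage1_order = [mv.rsid for mv in dissimilarity if mv.rsid in stage1_ids]
        (out / "stage1_snps.txt").write_text("".join(s + "\n" for s in stage1_order))
        manifest["counts"]["stage1_union"] = len(selected)
        manifest["counts"]["stage1"] = len(stage1_order)

        # -- stage 2 ---------------------------------------------------------
        stage = "stage2"
        if not stage1_order:
            raise ValueError("stage 1 selected no SNPs (no alpha=beta=1 site)")
        stage1_variants = [mv for mv in dissimilarity if mv.rsid in stage1_ids]
        matrix = encode_symbols(stage1_variants, sample_ids, train_ids)
        features_all = allele_context_matrix(
            [mv.record for mv in dissimilarity], sample_ids
        )
        if config.eps_grid:
            def _eval26(outlier_ids: list[str]) -> float:
                return panel_accuracy(
                    outlier_ids, features_all, meta, (train_ids, test_ids),
                    task="26pop", clf_params=config.clf_params,
                )

            eps_used, labels = scan_epsilon(
                matrix, config.eps_grid, _eval26, min_pts=config.min_pts
            )
        else:
            eps_used = config.eps
            labels = dbscan(matrix, eps=config.eps, min_pts=config.min_pts)
        candidates = select_outliers(matrix, labels)
        if not candidates:
            raise ValueError(f"DBSCAN at eps={eps_used} left no outlier SNPs")
        (out / "stage2_snps.txt").write_text("".join(s + "\n" for s in candidates))
        manifest["counts"]["stage2_clusters"] = max(0, int(labels.max())) if labels.size else 0
        manifest["counts"]["stage2_outliers"] = len(candidates)
        manifest["eps"] = float(eps_used)

        # -- performance matrix ---------------------------------------------
        stage = "performance"
        perf = build_performance_matrix(
            candidates, features_all, meta, (train_ids, test_ids),
            clf_params=config.clf_params,
        )
        perf.to_frame().to_csv(out / "perf.tsv", sep="\t", float_format="%.6f")

        # -- continental panel ----------------------------------------------
        stage = "panel"
        th_grid = config.th_grid if config.th_grid else list(default_threshold_grid())
        table, panel = scan_thresholds(
            perf, features_all, meta, (train_ids, test_ids), th_grid,
            task="continental", size_cap=config.size_cap, clf_params=config.clf_params,
        )
        table.to_csv(out / "scan_continental.tsv", sep="\t", index=False,
                     float_format="%.6f")
        (out / "panel_continental.txt").write_text(
            "".join(s + "\n" for s in panel.snp_ids)
        )
        manifest["counts"]["panel_continental"] = len(panel)
        manifest["continental"] = {
            "threshold": float(panel.threshold),
            "panel_size": len(panel),
            "accuracy": float(panel.accuracy),
        }

        # -- continental classification report -------------------------------
        stage = "classify"
        pop_of = dict(zip(meta["sample_id"], meta["population"]))
        cont_of = population_to_continent(meta)
        y_train = np.array([cont_of[pop_of[s]] for s in train_ids])
        y_test = np.array([cont_of[pop_of[s]] for s in test_ids])
        X_train = features_all.loc[train_ids, panel.snp_ids].to_numpy(float)
        X_test = features_all.loc[test_ids, panel.snp_ids].to_numpy(float)
        clf = SoftmaxClassifier(**config.clf_params).fit(X_train, y_train)
        acc, confusion, per_cont = evaluate(clf, X_test, y_test, cont_of)
        report = {
            "task": "continental",
            "accuracy": acc,
            "panel_size": len(panel),
            "threshold": float(panel.threshold),
            "seed": config.seed,
            "hyperparameters": config.clf_params,
            "confusion_matrix": {
                "labels": list(confusion.index),
                "counts": confusion.to_numpy().tolist(),
            },
            "per_continent_accuracy": per_cont,
        }
        _write_json(report, out / "report_continental.json")
        manifest["continental"]["confusion_accuracy"] = acc

        # -- pairwise panels --------------------------------------------------
        stage = "pairwise"
        pairwise_rows = []
        for continent, s1, s2 in config.pairwise:
            ptable, ppanel = scan_thresholds(
                perf, features_all, meta, (train_ids, test_ids), th_grid,
                task="pairwise", pops=(s1, s2), continent=continent,
                size_cap=config.size_cap, clf_params=config.clf_params,
            )
            ptable.to_csv(out / f"scan_pairwise_{s1}_{s2}.tsv", sep="\t",
                          index=False, float_format="%.6f")
            pairwise_rows.append(
                {
                    "continent": continent,
                    "pair": f"{s1}-{s2}",
                    "n_snps": len(ppanel),
                    "threshold": float(ppanel.threshold),
                    "accuracy": float(ppanel.accuracy),
                }
            )
        if pairwise_rows:
            pd.DataFrame(pairwise_rows).to_csv(
                out / "pairwise_results.tsv", sep="\t", index=False,
                float_format="%.6f",
            )
        manifest["pairwise"] = pairwise_rows
    except Exception as exc:
        raise PipelineError(f"pipeline failed at stage '{stage}': {exc}") from exc

    _write_json(manifest, out / "manifest.json")
    logger.info("pipeline complete: %s", manifest["counts"])
    return manifest


def report(out_dir: str | Path) -> tuple[str, dict]:
    """Summarise a pipeline output directory (text + machine-readable dict).

    Missing artifacts are listed as absent rather than fatal.
    """
    out = Path(out_dir)
    summary: dict = {"absent": []}
    lines: list[str] = []
    manifest_p = out / "manifest.json"
    if manifest_p.exists():
        manifest = json.loads(manifest_p.read_text())
        summary["manifest"] = manifest
        lines.append("SNP selection funnel:")
        for key in ("input", "cleaned", "dissimilarity_set", "stage1",
                    "stage2_outliers", "panel_continental"):
            if key in manifest["counts"]:
                lines.append(f"  {key:>20}: {manifest['counts'][key]}")
    else:
        summary["absent"].append("manifest.json")
    rep_p = out / "report_continental.json"
    if rep_p.exists():
        rep = json.loads(rep_p.read_text())
        summary["continental"] = rep
        lines.append(
            f"Continental: {rep['accuracy']:.2f}% with {rep['panel_size']} SNPs "
            f"(th={rep['threshold']:.2f})"
        )
        labels = rep["confusion_matrix"]["labels"]
        lines.append("Confusion matrix (rows = truth):")
        lines.append("  " + "\t".join(["", *labels]))
        for lab, row in zip(labels, rep["confusion_matrix"]["counts"]):
            lines.append("  " + "\t".join([lab, *map(str, row)]))
    else:
        summary["absent"].append("report_continental.json")
    pw_p = out / "pairwise_results.tsv"
    if pw_p.exists():
        pw = pd.read_csv(pw_p, sep="\t")
        summary["pairwise"] = pw.to_dict(orient="records")
        lines.append("Pairwise panels:")
        lines.append(pw.to_string(index=False))
    else:
        summary["absent"].append("pairwise_results.tsv")
    return "\n".join(lines) + "\n", summary
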