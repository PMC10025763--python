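"""End-to-end orchestration: simulate -> train -> explain -> protocols -> genes.

A :class:`RunConfig` (loadable from YAML) fixes the cohort design, the model
ensemble, the reference spec, the protocol grid and the analysis thresholds;
``run_pipeline`` executes the stages in order into a run directory and writes
a manifest with the config hash and all derived seeds, so a rerun with the
same config reproduces the reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as gio
from .genes import (
    differential_expression,
    housekeeping_genes,
    marker_recall,
    tissue_specific_genes,
    top_contributing_genes,
)
from .models import ModelConfig, accuracy, train
from .protocols import aggregation_protocol
from .references import ReferenceSpec, build_reference_pool, gene_stats
from .syndata import SyntheticDesign, generate_cohort, split_train_test


@dataclass
class RunConfig:
    design: SyntheticDesign = field(default_factory=SyntheticDesign)
    arch: str = "MLP"
    n_models: int = 4
    max_epochs: int = 30
    explainer: str = "DeepLift"
    reference_kind: str = "zero"
    reference_pool_size: int = 100
    aggregation_grid: tuple = (1, 2, 4)
    top_k: int = 100
    fdr_threshold: float = 0.001
    fold_threshold: float = 3.0
    split_ratio: float = 0.9
    seed: int = 0

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text()) or {}
        design = SyntheticDesign(**raw.pop("design", {}))
        cfg = cls(design=design, **raw)
        if "aggregation_grid" in raw:
            cfg.aggregation_grid = tuple(raw["aggregation_grid"])
        return cfg

    def to_dict(self):
        d = asdict(self)
        d["aggregation_grid"] = list(self.aggregation_grid)
        return d


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def train_ensemble(train_matrix, arch, n_models, base_seed, max_epochs=30, **cfg_kwargs):
    """Train n models differing only in their seeds (init, shuffling, dropout)."""
    models = []
    for i in range(n_models):
        cfg = ModelConfig(
            arch=arch,
            n_genes=train_matrix.n_genes,
            n_classes=len(train_matrix.tissues),
            max_epochs=max_epochs,
            seed=base_seed + 1000 * (i + 1),
            **cfg_kwargs,
        )
        models.append(train(train_matrix, cfg))
    return models


def run_pipeline(config: RunConfig, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "config_hash": config_hash(config), "outputs": []}

    # 1. simulate
    design = replace(config.design, seed=config.seed)
    matrix, truth = generate_cohort(design)
    gio.write_matrix(matrix, outdir / "expression.tsv")
    gio.write_ground_truth(truth, outdir / "ground_truth.json")
    manifest["outputs"] += ["expression.tsv", "ground_truth.json"]

    train_m, test_m = split_train_test(matrix, config.split_ratio, seed=config.seed + 7)

    # 2. train
    models = train_ensemble(train_m, config.arch, config.n_models, config.seed, max_epochs=config.max_epochs)
    accs = [accuracy(m, test_m) for m in models]
    for i, m in enumerate(models):
        m.history.to_csv(outdir / f"model{i}_history.csv", index=False)
        manifest["outputs"].append(f"model{i}_history.csv")

    # 3. references + explain + aggregation protocol on one test sample per tissue
    stats = gene_stats(train_m)
    spec = ReferenceSpec(kind=config.reference_kind, pool_size=config.reference_pool_size, seed=config.seed + 11)
    pool = build_reference_pool(spec, stats)
    gene_ids = np.asarray(matrix.gene_ids)

    protocol_curves = {}
    tissue_scores = {}
    normal_tissues = [t for t in matrix.tissues if not t.endswith("_cancer")]
    for tissue in normal_tissues:
        idx = test_m.samples_of(tissue)
        if len(idx) == 0:
            continue
        sample = test_m.values[idx[0]]
        curve, reports = aggregation_protocol(
            sample, models, config.explainer, tissue, gene_ids,
            n_grid=[n for n in config.aggregation_grid if n <= len(models)],
            k=config.top_k, seed=config.seed + 13,
            opts={"reference": pool[0], "reference_pool": pool, "dropout_enabled": True},
        )
        curve.to_csv(outdir / f"aggregation_{tissue}.csv", index=False)
        manifest["outputs"].append(f"aggregation_{tissue}.csv")
        protocol_curves[tissue] = curve
        # tissue-level attribution: mean over models and evaluation samples
        per_sample = []
        for j in idx[: min(len(idx), 5)]:
            vecs = [
                _model_scores(m, test_m.values[j], config, tissue, pool)
                for m in models
            ]
            per_sample.append(np.mean(vecs, axis=0))
        tissue_scores[tissue] = np.asarray(per_sample)

    # 4. genes stage
    hk = housekeeping_genes(matrix)
    ts = tissue_specific_genes(matrix)
    gene_report = {
        "hk_recovered": sorted(hk & truth.hk_genes),
        "n_hk_called": len(hk),
        "marker_recall_topk": {},
        "model_test_accuracy": accs,
    }
    for tissue, scores in tissue_scores.items():
        top = top_contributing_genes(scores, gene_ids, level="tissue", k=config.top_k)
        gene_report["marker_recall_topk"][tissue] = marker_recall(top, truth.markers[tissue])

    cancer_classes = [t for t in matrix.tissues if t.endswith("_cancer")]
    de_summary = {}
    for c in cancer_classes:
        normal_name = c[: -len("_cancer")]
        res = differential_expression(
            matrix.subset(matrix.samples_of(normal_name)),
            matrix.subset(matrix.samples_of(c)),
            fdr_threshold=config.fdr_threshold,
            fold_threshold=config.fold_threshold,
        )
        planted = {g for g, _, _ in truth.de_genes[c]}
        de_summary[c] = {
            "n_pass": int(res.table["passed"].sum()),
            "planted_recovered": len(res.passing & planted),
            "n_planted": len(planted),
        }
    gene_report["differential_expression"] = de_summary
    gio.write_report(gene_report, outdir / "gene_report.json")
    manifest["outputs"].append("gene_report.json")

    gio.write_report(manifest, outdir / "manifest.json")
    return {
        "manifest": manifest,
        "models": models,
        "accuracies": accs,
        "protocol_curves": protocol_curves,
        "gene_report": gene_report,
    }


def _model_scores(model, sample, config: RunConfig, target, pool):
    from .explainers import explain

    return explain(
        config.explainer, model, sample, target,
        reference=pool[0], reference_pool=pool,
        dropout_enabled=False,
    ).scores
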