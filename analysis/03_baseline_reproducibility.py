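"""Reproducibility of each explainer without optimization: intra-model
(5 dropout-perturbed replicates on one model) and inter-model (one replicate
from each of 5 models), scored by pairwise Spearman and top-100 overlap.

Writes results/baseline_reproducibility.csv. Finding: single-pass
attributions are poorly reproducible for most explainers (inter-model
Spearman well below 1), which motivates the optimization protocols.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import genexplain as gx
from genexplain import io as gio
from genexplain.explainers import MLP_EXPLAINERS, explain
from genexplain.pipeline import train_ensemble
from genexplain.protocols import ReplicateSet, pairwise_report
from genexplain.references import ReferenceSpec, build_reference_pool, gene_stats

ROOT = Path(__file__).resolve().parents[1]
SEED = 1

matrix = gio.read_matrix(ROOT / "scratch" / "cohort" / "expression.tsv")
train_m, test_m = gx.split_train_test(matrix, 0.9, seed=SEED)
models = train_ensemble(train_m, "MLP", 5, base_seed=SEED, max_epochs=40)
gene_ids = np.asarray(matrix.gene_ids)

stats = gene_stats(train_m)
pool = build_reference_pool(ReferenceSpec(kind="universal", pool_size=200, seed=SEED), stats)
sample = test_m.values[0]
target = test_m.tissue_labels[0]

rows = []
for explainer in MLP_EXPLAINERS:
    kwargs = dict(reference=pool[0], reference_pool=pool, dropout_enabled=True)
    intra = np.stack([
        explain(explainer, models[0], sample, target, seed=SEED * 100 + r, **kwargs).scores
        for r in range(5)
    ])
    inter = np.stack([
        explain(explainer, m, sample, target, seed=SEED * 200 + i, **kwargs).scores
        for i, m in enumerate(models)
    ])
    for axis, vecs in [("intra_model", intra), ("inter_model", inter)]:
        rep = pairwise_report(ReplicateSet(vecs, gene_ids, axis=axis), k=100)
        rows.append({"explainer": explainer, "axis": axis,
                     "mean_spearman": rep.mean_spearman, "mean_overlap": rep.mean_overlap})

frame = pd.DataFrame(rows)
frame.to_csv(ROOT / "results" / "baseline_reproducibility.csv", index=False)
print(frame.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
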