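"""Generate the study cohort: a synthetic multi-tissue transcriptome with
planted tissue markers, housekeeping genes and paired cancer classes.

Writes the expression matrix and ground truth to scratch/cohort/ (large
files) and a design summary to results/cohort_summary.json.
"""

import json
from pathlib import Path

import numpy as np

import genexplain as gx
from genexplain import io as gio

ROOT = Path(__file__).resolve().parents[1]
SEED = 1

design = gx.SyntheticDesign(seed=SEED)  # defaults: 4 tissues, 1000 genes, 50 samples/tissue
matrix, truth = gx.generate_cohort(design)

out = ROOT / "scratch" / "cohort"
out.mkdir(parents=True, exist_ok=True)
gio.write_matrix(matrix, out / "expression.tsv")
gio.write_ground_truth(truth, out / "ground_truth.json")

summary = {
    "n_samples": matrix.n_samples,
    "n_genes": matrix.n_genes,
    "classes": matrix.tissues,
    "markers_per_tissue": {t: len(s) for t, s in truth.markers.items()},
    "n_hk_genes": len(truth.hk_genes),
    "de_genes_per_cancer": {c: len(v) for c, v in truth.de_genes.items()},
    "value_range_log2": [float(matrix.values.min()), float(matrix.values.max())],
}
(ROOT / "results").mkdir(exist_ok=True)
(ROOT / "results" / "cohort_summary.json").write_text(json.dumps(summary, indent=1))

print(f"cohort: {matrix.n_samples} samples x {matrix.n_genes} genes")
print(f"classes: {', '.join(matrix.tissues)}")
print(f"planted: {sum(len(s) for s in truth.markers.values())} markers, "
      f"{len(truth.hk_genes)} HK genes, "
      f"{sum(len(v) for v in truth.de_genes.values())} DE genes")
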