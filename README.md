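# genexplain

Reproducibility benchmarking and optimization of gradient-based explainers
for transcriptomic tissue classifiers.

## The problem

Neural-network classifiers trained on bulk RNA-seq expression profiles
(log₂(TPM+1) per gene) can assign tissue or tumor type with high accuracy,
and backprop attribution methods promise to turn them into marker-gene
discovery tools: the genes with the largest contribution scores for a
sample are candidate markers for its class. In practice a single
attribution pass is unstable — two equally accurate models, or two
dropout-perturbed passes over the same model, can rank very different genes
at the top. This package is a framework for **measuring** that instability
and for **optimizing it away by averaging**, aimed at computational
biologists who want explanation-derived gene lists they can trust.

It provides:

* MLP and CNN tissue classifiers over expression vectors (the CNN places
  genes row-major into a square grid with zero padding), trained with Adam,
  per-epoch class up-sampling and a reduce-on-plateau learning-rate
  schedule — implemented on a small numpy reverse-mode engine that exposes
  the custom backward passes the explainers need;
* eight from-scratch attribution methods: Saliency, Input×Gradient, guided
  backpropagation, Integrated Gradients (midpoint rule), DeepLIFT (Rescale
  rule), DeepLiftShap, Guided Grad-CAM and Guided Grad-CAM++ (CNN only);
* four baseline **references** for the difference-from-reference methods:
  zero, truncated-N(0,1) noise, and per-gene truncated N(μ_g, σ_g) built
  from all tissues ("universal") or one tissue ("specific");
* four optimization **protocols** that trace reproducibility against the
  number of averaged estimates: noise-added repeats (SmoothGrad style),
  simple repeats (variability from enabled dropout), reference counts, and
  model aggregation;
* a **genes** stage: top-k contributing genes, housekeeping and
  tissue-enhanced classification on the TPM scale, Mann–Whitney
  differential expression with Benjamini–Hochberg FDR and fold-change
  filters, annotation enrichment, and shared top contributing genes;
* a synthetic-cohort generator with planted ground truth (markers, HK
  genes, DE effects), so every claim is checkable against known truth.

## The statistics at the core

For a replicate set of attribution vectors a⁽¹⁾, …, a⁽ⁿ⁾ over the same
genes, reproducibility is summarized over all C(n,2) pairs by Spearman's ρ
of the scores and by |top₁₀₀(a⁽ⁱ⁾) ∩ top₁₀₀(a⁽ʲ⁾)| / 100. The
difference-from-reference methods satisfy their defining axiom
Σᵢ aᵢ = F(x) − F(x₀) (completeness / summation-to-delta), which the test
suite verifies on random networks. The aggregation protocol forms, for
each aggregation size n out of M models, K = max(⌈M/n⌉, 4) replicates
(each the mean attribution over n sampled models) and scores all C(K,2)
pairs.

## Worked example

```python
import numpy as np, genexplain as gx
from genexplain.pipeline import train_ensemble
from genexplain.protocols import aggregation_protocol

design = gx.SyntheticDesign(n_tissues=3, n_genes=800, n_samples_per_tissue=50,
                            noise_sd=0.3, cancer_fraction=0.0, seed=1)
matrix, truth = gx.generate_cohort(design)
train, test = gx.split_train_test(matrix, 0.9, seed=1)          # 9:1 per tissue
models = train_ensemble(train, "MLP", 12, base_seed=10, max_epochs=40)

curve, _ = aggregation_protocol(
    test.values[0], models, "DeepLift", test.tissue_labels[0],
    np.asarray(matrix.gene_ids), n_grid=[1, 10], seed=1,
    opts={"reference": np.zeros(800), "dropout_enabled": True})
print(curve[["n", "mean_spearman"]])
```

prints (seed 1):

```
    n  mean_spearman
0   1       0.203039
1  10       0.912231
```

i.e. single-model DeepLift attributions of the same sample correlate at
ρ ≈ 0.20 across models, while averaging 10 models lifts agreement to
ρ ≈ 0.91 — the aggregation effect the framework is built to quantify. The
numbered scripts under `analysis/` run the full narrative (simulate →
train → baseline reproducibility → the four protocols → gene-level
relevance) and write their tables under `results/`.

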