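# Methods

## Synthetic cohorts

The generator emulates the structure of a large multi-tissue RNA-seq
compendium on the log₂(TPM+1) scale. Each gene receives a background level
drawn from N(3.5, 1.5²) on the log₂ scale, clipped at 0 — a right-skewed,
log-normal-like TPM background with median ≈ 10 TPM. Planted structure:

* **Markers** (default 25 per tissue, fold 4): the effect is added on the
  log₂(TPM+1) scale, i.e. multiplicatively on TPM+1, so in the noise-free
  case the per-tissue median log₂ difference equals log₂(effect) exactly.
* **Housekeeping genes** (default 50 at 50 TPM): fixed at
  log₂(hk_level+1) in every class, giving per-tissue medians well inside
  the 2-fold HK rule.
* **Cancer classes**: a configurable fraction of tissues receives a paired
  class that copies the normal profile and shifts planted DE genes by the
  nominal fold **exactly on the TPM scale** (up or down, direction
  recorded). DE genes are taken from the highest-baseline unplanted genes;
  for a down-regulated 4-fold gene the median-TPM ratio is exact in the
  profile, and the realized ratio in a finite cohort carries only
  median-sampling noise (≈5% multiplicative SE at n=50, σ=0.3). The
  realized-fold check in the tests is therefore stated for the bulk of
  genes (≥90% within 10%) and for the cross-gene median (within 5%), not
  per gene almost-surely.
* i.i.d. Gaussian noise (default σ=0.3) is added on the log₂ scale and
  values are clipped at 0.

Defaults (4 tissues, 50 samples each, 1000 genes, cancer fraction 0.5) are
desk-scale: large enough that classifiers are non-trivial and attribution
rankings are meaningfully noisy, small enough that the full analysis runs
in seconds. What the generator does **not** model: read-count sampling,
library-size or batch effects, gene–gene correlation beyond the planted
classes, and biological heterogeneity within a tissue. Passing tests show
the machinery is correct and that the averaging protocols behave as
designed under known ground truth; they do not certify effect sizes on
real compendia.

One quirk worth knowing: the tissue-enhanced (TS) surrogate rule compares
a tissue's median against the mean of **all** other classes, including a
paired cancer class that shares the tissue's markers. Markers of a tissue
with a cancer pair therefore often miss the TS call at fold 5 — visible in
`analysis/05_gene_relevance.py` — while markers of unpaired tissues are
recovered fully. This mirrors how a real tissue-enrichment tool would
behave when a transcriptionally similar class is present.

## Classifiers

* **MLP**: input → dense(128) → batch norm → ReLU → dropout(0.25) →
  dense(classes). Learning rate 0.001.
* **CNN**: genes placed row-major into the smallest square grid covering
  n_genes (zero padding at the tail; the gene→cell permutation is part of
  the model config), then three blocks of convolution (channels 64/128/256,
  kernels 5/5/3, stride 1, 'same' padding) → max-pool(2) → batch norm →
  ReLU, then dropout(0.25) → global average pooling → batch norm → ReLU →
  dense(classes). Learning rate 0.0006.

Training: Adam on softmax cross-entropy, batch size 256, L2 penalty 0.001
on weight matrices, per-epoch up-sampling (every class resampled with
replacement to the majority count, so each epoch presents balanced
classes). When the training loss fails to improve by more than 1e-4 for 5
consecutive epochs the learning rate is multiplied by 0.25 ("reduce by
0.25" is read as the multiply-by-factor plateau convention; the factor and
the improvement tolerance are configurable, and the plateau is measured on
training loss since no validation stream is part of the schedule).
Weight initialization is He fan-in scaling with zero biases, seeded per
model; batch-norm runs in evaluation mode at prediction and explanation
time, making both pure functions of (parameters, input).

Everything runs on a small numpy reverse-mode engine (`genexplain.nn`)
written for this package: the explainers require three different backward
rules through the same graph (plain gradients, guided-ReLU gradients, and
DeepLIFT multipliers over a pair of forward passes), which is exactly what
generic autodiff does not expose.

## Explainers

All methods attribute the **pre-softmax score of the sample's true class**
(configurable). With dropout enabled, one mask per call is drawn from the
seed and shared by every forward/backward pass inside the call — a call
sees a single thinned architecture, and repeated calls with fresh seeds
are the source of intra-model variability. Batch-norm statistics stay
frozen.

* **Saliency** returns |gradient| (signed variant behind a flag).
* **IntegratedGradients** uses midpoint Riemann quadrature with n_steps=50
  by default. Along the straight path the directional derivative of a
  ReLU net is piecewise constant with jumps where units cross zero, so the
  quadrature error is O(#kinks/n_steps): exact (machine precision) when
  the path crosses no kink, and decaying like 1/n otherwise. The tests
  check completeness at machine tolerance on kink-free paths and at the
  analytic O(1/n) tolerance on kink-crossing ones.
* **DeepLift** implements the Rescale rule: affine stages (dense, conv,
  eval-mode batch norm, dropout masks) propagate multipliers like
  gradients; each ReLU uses Δout/Δin between the sample and reference
  passes, with a gradient fallback when |Δin| < 1e-7. Max-pool routes the
  multiplier to the sample-pass argmax rescaled so that the selected
  cell's delta carries the pooled delta; summation-to-delta is exact
  except through the tiny-delta fallback. RevealCancel is out of scope.
* **DeepLiftShap** averages DeepLift over n references drawn without
  replacement from a pool (one dropout mask per call, shared across
  references).
* **GuidedBackprop** additionally zeroes the backward signal at each ReLU
  where it is negative. Note the input-level scores need not carry the
  plain gradient's signs: masking happens at ReLU layers and the first
  linear layer can re-mix signs.
* **Guided Grad-CAM / ++** (CNN only): the class-activation map over the
  last conv block's ReLU output (Grad-CAM weights = spatially averaged
  gradients; Grad-CAM++ uses the closed-form α-weighted positive
  gradients), ReLU-rectified, bilinearly upsampled to the input grid and
  multiplied by the guided-backprop signal of each gene's cell. Pad-cell
  attributions are discarded by the grid→gene mapping (their magnitude is
  kept on the reshape layer for auditing).

## References

Four kinds, all on the log₂(TPM+1) scale: zero; i.i.d. truncated N(0,1)
on [0,1]; and per-gene truncated N(μ_g, σ_g) with moments over all samples
("universal") or one tissue's samples ("specific"). σ uses the sample
(n−1) convention. The truncation interval for universal/specific is
configurable: `paper_literal` restricts to [0, σ] (implemented verbatim),
while the default `symmetric` uses [max(0, μ−σ), μ+σ], which keeps
references near realistic expression (with μ typically well above σ, a
[0, σ] interval sits far below observed values; both modes are persisted
in metadata so either convention can be reproduced). Sampling uses the
analytic inverse-CDF of the truncated normal; σ=0 genes emit μ clamped
into the interval. Pools default to 2000 vectors; the zero pool repeats
the same vector.

## Protocols

All four protocols score a `ReplicateSet` by pairwise Spearman (average
ranks on ties; a constant vector yields a missing value with a warning)
and top-k overlap (k=100, descending score, deterministic gene-ID
tie-break).

* **SmoothGrad repeats**: per model, a pool of 50 pseudo-samples (gene-wise
  N(0, σ) noise on the log₂ scale, unclipped by default) is attributed
  once; for each n the mean over n pool draws forms one replicate per
  model, compared across models.
* **Simple repeats**: identical but the unmodified sample is attributed 50
  times with dropout enabled.
* **Reference counts**: for DeepLift/DeepLiftShap/IntegratedGradients, the
  attribution for n references is the mean over n pool-drawn baselines
  (per-reference attributions are cached, draws are seeded per model).
* **Aggregation**: each of M models is attributed once; for each n,
  K = max(⌈M/n⌉, 4) aggregated replicates (means over n models drawn
  without replacement) are formed and all C(K,2) pairs scored. The K rule
  is the decreasing-budget reading of the protocol; a literal K=60n
  override is kept behind `k_rule="literal"`.

Inter-model comparisons are computed per sample (the per-tissue-mean
variant is available by averaging attributions first). Cross-explainer
consistency is a symmetric top-k-overlap matrix over (explainer, config)
gene lists, ordered by average-linkage clustering on 1−overlap.

## Gene-level analyses

Classification works on back-transformed TPM: HK = per-tissue median
TPM ≥ 1 everywhere and max/min median < 2; tissue-enhanced = median in
tissue t ≥ 1 TPM and ≥ 5× the mean of other tissues' medians (a
documented surrogate for an external tissue-enrichment tool). Differential
expression = per-gene two-sided Mann–Whitney U (tie-corrected normal
approximation for the group sizes used) with Benjamini–Hochberg FDR across
genes; a gene passes at FDR ≤ 0.001 and median-TPM fold ≥ 3 (pseudocount
0.01 TPM). Expression summaries use medians throughout (means behind a
flag is deliberately not offered; medians are what the rules are defined
on). Enrichment of an annotation in a gene list is observed/expected with
expected = |set|·|annotation|/|universe|. Shared top contributing genes
of a group are those in the top-k of ≥ 2 of its samples.

## Problem sizes and determinism

The analysis scripts and the acceptance script use desk-scale dimensions —
3–4 tissues, 800–1000 genes, 50 samples per class, ensembles of 5–12 MLPs —
chosen so the full pipeline runs in seconds while leaving attribution
rankings genuinely noisy at n=1 (single-model DeepLift Spearman ≈ 0.2 on
the default cohort), which is the regime the protocols are about. All
randomness flows from explicit seeds through hierarchical `SeedSequence`
spawning (cohort → gene/sample noise; protocol → model → draw), so every
table is bit-reproducible on one platform; cross-platform agreement is
tolerance-based through floating-point reduction order.

## Known limitations

* Full-scale dimensions (tens of thousands of genes, dozens of classes,
  60-model ensembles) are supported by configuration but not exercised by
  the shipped analyses.
* DeepLIFT through max-pool uses the argmax-routing rule described above;
  alternative pooling conventions exist and can change CNN attributions.
* The CNN explainers drop zero-pad cells by construction; genes cannot
  receive pad attributions, but the pad total is only logged, not
  redistributed.
* The TS surrogate is a fold-rule, not a reimplementation of any external
  enrichment tool; its thresholds are the documented defaults.
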