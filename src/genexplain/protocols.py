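"""Reproducibility metrics and explainer-optimization protocols.

The reproducibility of an explainer is measured over a set of replicate
attribution vectors for one (sample, explainer) pair: every unordered pair
of replicates is scored by Spearman's rank correlation of the gene scores
and by the fraction of shared gene IDs among the top-k (default k=100)
contributing genes.

Four protocols trace how reproducibility responds to averaging:

* ``smoothgrad_protocol``     — average attributions of n noisy pseudo-samples
  (noise N(0, noise_sd) added per gene on the log2 scale);
* ``simple_repeat_protocol``  — average n repeated attributions of the
  unmodified sample (variability comes from enabled dropout);
* ``reference_count_protocol``— average attributions over n references drawn
  from a background pool (reference-based explainers only);
* ``aggregation_protocol``    — average attributions over n independently
  trained models; for each n, K = max(ceil(M/n), 4) aggregated replicates are
  formed and all C(K, 2) pairs scored.

The first three build one replicate per model and compare across models;
aggregation compares across resampled model subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import ceil, comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .explainers import REFERENCE_EXPLAINERS, deeplift, integrated_gradients, explain


def spearman(a, b):
    """Spearman rank correlation (average ranks for ties); NaN when a vector is constant."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-D vectors of length >= 3")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("scores must be finite")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant score vector: Spearman undefined, reporting NaN")
        return float("nan")
    rho, _ = sps.spearmanr(a, b)
    return float(rho)


def rank_genes(scores, gene_ids):
    """Gene IDs sorted by descending score, ties broken by gene ID (ascending)."""
    gene_ids = np.asarray(gene_ids)
    order = np.lexsort((gene_ids, -np.asarray(scores, dtype=float)))
    return gene_ids[order]


def topk_overlap(a, b, gene_ids, k=100):
    """|top_k(a) intersection top_k(b)| / k."""
    if k > len(gene_ids):
        raise ValueError("k exceeds the gene universe")
    ta = set(rank_genes(a, gene_ids)[:k])
    tb = set(rank_genes(b, gene_ids)[:k])
    return len(ta & tb) / k


@dataclass
class ReplicateSet:
    """Attribution score vectors sharing one (sample, explainer) context."""

    vectors: np.ndarray  # (n_replicates, n_genes)
    gene_ids: np.ndarray
    axis: str = "intra_model"

    def __post_init__(self):
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        self.gene_ids = np.asarray(self.gene_ids)
        if self.vectors.shape[0] < 2:
            raise ValueError("a replicate set needs >= 2 replicates")
        if self.vectors.shape[1] != len(self.gene_ids):
            raise ValueError("gene universe mismatch")

    @property
    def n_replicates(self):
        return self.vectors.shape[0]


@dataclass
class ReproducibilityReport:
    pairwise_spearman: list
    pairwise_topk_overlap: list
    k: int
    axis: str
    params: dict = field(default_factory=dict)

    @property
    def n_pairs(self):
        return len(self.pairwise_spearman)

    @property
    def mean_spearman(self):
        return float(np.nanmean(self.pairwise_spearman))

    @property
    def sd_spearman(self):
        return float(np.nanstd(self.pairwise_spearman))

    @property
    def mean_overlap(self):
        return float(np.mean(self.pairwise_topk_overlap))

    @property
    def sd_overlap(self):
        return float(np.std(self.pairwise_topk_overlap))


def pairwise_report(rep_set: ReplicateSet, k=100, params=None) -> ReproducibilityReport:
    """All C(n, 2) replicate pairs scored by Spearman and top-k overlap."""
    rhos, overlaps = [], []
    for i, j in combinations(range(rep_set.n_replicates), 2):
        rhos.append(spearman(rep_set.vectors[i], rep_set.vectors[j]))
        overlaps.append(topk_overlap(rep_set.vectors[i], rep_set.vectors[j], rep_set.gene_ids, k=k))
    assert len(rhos) == comb(rep_set.n_replicates, 2)
    return ReproducibilityReport(rhos, overlaps, k=k, axis=rep_set.axis, params=params or {})


def _curve_frame(reports: dict) -> pd.DataFrame:
    rows = [
        {
            "n": n,
            "mean_spearman": r.mean_spearman,
            "sd_spearman": r.sd_spearman,
            "mean_overlap": r.mean_overlap,
            "sd_overlap": r.sd_overlap,
            "n_pairs": r.n_pairs,
        }
        for n, r in sorted(reports.items())
    ]
    return pd.DataFrame(rows)


def _attribute_once(model, sample, explainer_id, target_class, opts, seed):
    return explain(
        explainer_id,
        model,
        sample,
        target_class,
        reference=opts.get("reference"),
        reference_pool=opts.get("reference_pool"),
        n_steps=opts.get("n_steps", 50),
        n_references=opts.get("n_references", 1),
        dropout_enabled=opts.get("dropout_enabled", False),
        seed=seed,
    ).scores


def smoothgrad_protocol(sample, models, explainer_id, target_class, gene_ids, n_grid,
                        noise_sd=1.0, pool_size=50, k=100, seed=0, opts=None):
    """SmoothGrad-style curve: reproducibility across models of n-pseudo-sample averages."""
    if len(models) < 2:
        raise ValueError("need >= 2 models")
    opts = dict(opts or {})
    n_grid = sorted(set(n_grid))
    if max(n_grid) > pool_size:
        raise ValueError("n_pseudo exceeds the pseudo-sample pool")
    sample = np.asarray(sample, dtype=float)
    root = np.random.SeedSequence(seed)
    model_seeds = root.spawn(len(models))
    per_model_scores = []
    for m_i, model in enumerate(models):
        rng = np.random.default_rng(model_seeds[m_i])
        noise = rng.normal(0.0, noise_sd, size=(pool_size, len(sample))) if noise_sd > 0 else np.zeros((pool_size, len(sample)))
        scores = np.stack([
            _attribute_once(model, sample + noise[p], explainer_id, target_class, opts,
                            seed=int(rng.integers(2**31)))
            for p in range(pool_size)
        ])
        per_model_scores.append((scores, np.random.default_rng(model_seeds[m_i].spawn(1)[0])))
    reports = {}
    for n in n_grid:
        vectors = []
        for scores, rng in per_model_scores:
            idx = rng.choice(pool_size, size=n, replace=False)
            vectors.append(scores[idx].mean(axis=0))
        rep = ReplicateSet(np.stack(vectors), gene_ids, axis="inter_model")
        reports[n] = pairwise_report(rep, k=k, params={"protocol": "smoothgrad", "noise_sd": noise_sd, "n": n})
    return _curve_frame(reports), reports


def simple_repeat_protocol(sample, models, explainer_id, target_class, gene_ids, n_grid,
                           pool_size=50, k=100, seed=0, opts=None):
    """Simple-repeat curve: n dropout-perturbed repeats averaged per model."""
    if len(models) < 2:
        raise ValueError("need >= 2 models")
    opts = dict(opts or {})
    opts.setdefault("dropout_enabled", True)
    n_grid = sorted(set(n_grid))
    if max(n_grid) > pool_size:
        raise ValueError("n_repeats exceeds the repeat pool")
    sample = np.asarray(sample, dtype=float)
    root = np.random.SeedSequence(seed)
    model_seeds = root.spawn(len(models))
    per_model = []
    for m_i, model in enumerate(models):
        rng = np.random.default_rng(model_seeds[m_i])
        scores = np.stack([
            _attribute_once(model, sample, explainer_id, target_class, opts, seed=int(rng.integers(2**31)))
            for _ in range(pool_size)
        ])
        per_model.append((scores, np.random.default_rng(model_seeds[m_i].spawn(1)[0])))
    reports = {}
    for n in n_grid:
        vectors = []
        for scores, rng in per_model:
            idx = rng.choice(pool_size, size=n, replace=False)
            vectors.append(scores[idx].mean(axis=0))
        rep = ReplicateSet(np.stack(vectors), gene_ids, axis="inter_model")
        reports[n] = pairwise_report(rep, k=k, params={"protocol": "simple_repeat", "n": n})
    return _curve_frame(reports), reports


def reference_count_protocol(sample, models, explainer_id, target_class, gene_ids,
                             reference_pool, n_grid, k=100, seed=0, opts=None):
    """Reference-count curve for explainers that require a baseline."""
    if explainer_id not in REFERENCE_EXPLAINERS:
        raise ValueError(f"{explainer_id} does not take references")
    if len(models) < 2:
        raise ValueError("need >= 2 models")
    opts = dict(opts or {})
    n_grid = sorted(set(n_grid))
    pool = np.atleast_2d(np.asarray(reference_pool, dtype=float))
    if max(n_grid) > pool.shape[0]:
        raise ValueError("n_refs exceeds the reference pool")
    sample = np.asarray(sample, dtype=float)
    root = np.random.SeedSequence(seed)
    model_seeds = root.spawn(len(models))

    def _scores_for_ref(model, ref, call_seed):
        if explainer_id == "IntegratedGradients":
            return integrated_gradients(model, sample, ref, target_class,
                                        n_steps=opts.get("n_steps", 50),
                                        dropout_enabled=opts.get("dropout_enabled", False), seed=call_seed)
        return deeplift(model, sample, ref, target_class,
                        dropout_enabled=opts.get("dropout_enabled", False), seed=call_seed)

    reports = {}
    per_model_cache = [dict() for _ in models]
    rngs = [np.random.default_rng(s) for s in model_seeds]
    for n in n_grid:
        vectors = []
        for m_i, model in enumerate(models):
            idx = rngs[m_i].choice(pool.shape[0], size=n, replace=False)
            acc = np.zeros(len(sample))
            for ri in idx:
                if ri not in per_model_cache[m_i]:
                    per_model_cache[m_i][ri] = _scores_for_ref(model, pool[ri], int(1000 * m_i + ri))
                acc += per_model_cache[m_i][ri]
            vectors.append(acc / n)
        rep = ReplicateSet(np.stack(vectors), gene_ids, axis="inter_model")
        reports[n] = pairwise_report(rep, k=k, params={"protocol": "references", "n": n})
    return _curve_frame(reports), reports


def aggregation_k(M, n, rule="ceil"):
    """Number of aggregated replicates for aggregation size n out of M models."""
    if not (1 <= n <= M):
        raise ValueError("need 1 <= n <= M")
    if rule == "literal":
        return max(60 * n, 4)
    return max(ceil(M / n), 4)


def aggregation_protocol(sample, models, explainer_id, target_class, gene_ids, n_grid,
                         k=100, seed=0, opts=None, k_rule="ceil"):
    """Model-aggregation curve: K = max(ceil(M/n), 4) replicates of n-model means."""
    opts = dict(opts or {})
    M = len(models)
    n_grid = sorted(set(n_grid))
    if max(n_grid) > M:
        raise ValueError("aggregation size exceeds the model count")
    sample = np.asarray(sample, dtype=float)
    root = np.random.SeedSequence(seed)
    model_seeds = root.spawn(M)
    base = np.stack([
        _attribute_once(model, sample, explainer_id, target_class, opts,
                        seed=int(np.random.default_rng(model_seeds[i]).integers(2**31)))
        for i, model in enumerate(models)
    ])
    draw_rng = np.random.default_rng(root.spawn(1)[0])
    reports = {}
    for n in n_grid:
        K = aggregation_k(M, n, rule=k_rule)
        vectors = np.stack([
            base[draw_rng.choice(M, size=n, replace=False)].mean(axis=0) for _ in range(K)
        ])
        rep = ReplicateSet(vectors, gene_ids, axis="aggregated")
        reports[n] = pairwise_report(rep, k=k, params={"protocol": "aggregation", "n": n, "K": K, "M": M})
    return _curve_frame(reports), reports


def cross_explainer_matrix(top_sets: dict, k=100):
    """Pairwise top-k overlap matrix across (explainer, config) gene sets.

    ``top_sets`` maps a configuration label to an iterable of gene IDs (the
    top-k list).  Returns (overlap DataFrame, clustered label order) using
    average-linkage hierarchical clustering on 1 - overlap.
    """
    labels = list(top_sets)
    sets = {lab: set(list(top_sets[lab])[:k]) for lab in labels}
    n = len(labels)
    mat = np.ones((n, n))
    for i, j in combinations(range(n), 2):
        ov = len(sets[labels[i]] & sets[labels[j]]) / k
        mat[i, j] = mat[j, i] = ov
    frame = pd.DataFrame(mat, index=labels, columns=labels)
    if n > 2:
        dist = squareform(1.0 - mat, checks=False)
        order = hierarchy.leaves_list(hierarchy.average(dist))
    else:
        order = np.arange(n)
    ordered = [labels[i] for i in order]
    return frame, ordered
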