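"""Biological relevance of top contributing genes.

Gene classification works on the TPM scale, back-transformed from the
log2(TPM+1) modeling scale:

* housekeeping (HK) genes — median TPM >= 1 in every tissue and < 2-fold
  spread of per-tissue medians;
* tissue-enhanced (TS) genes — a fold-over-other-tissues surrogate rule: a
  gene is enhanced in tissue t when its median TPM there is >= ``min_tpm``
  and >= ``fold_threshold`` times the mean of the other tissues' medians.

Differential expression between a normal and a cancer group uses a
two-sided Mann-Whitney U test per gene with Benjamini-Hochberg correction
across genes; a gene passes at FDR <= 0.001 and median-TPM fold change >= 3
(pseudocount 0.01 avoids division by zero).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .protocols import rank_genes, spearman

PSEUDOCOUNT = 0.01


def _median_tpm_by_tissue(matrix) -> pd.DataFrame:
    """Per-tissue median TPM table (tissues x genes)."""
    tpm = matrix.tpm()
    labels = np.asarray(matrix.tissue_labels)
    rows = {t: np.median(tpm[labels == t], axis=0) for t in matrix.tissues}
    return pd.DataFrame.from_dict(rows, orient="index", columns=matrix.gene_ids)


def top_contributing_genes(attributions, gene_ids, level="sample", k=100):
    """Ranked top-k gene lists from per-sample attribution score vectors.

    ``attributions``: array (n_samples, n_genes).  At ``level='tissue'`` the
    per-sample mean vector is ranked; at ``level='sample'`` a list per sample
    is returned.  Ranking is by descending score with gene-ID tie-break.
    """
    A = np.atleast_2d(np.asarray(attributions, dtype=float))
    if k > A.shape[1]:
        raise ValueError("k exceeds the gene universe")
    if not np.all(np.isfinite(A)):
        raise ValueError("attribution scores must be finite")
    if level == "tissue":
        return list(rank_genes(A.mean(axis=0), gene_ids)[:k])
    return [list(rank_genes(row, gene_ids)[:k]) for row in A]


def housekeeping_genes(matrix) -> set:
    """Genes with per-tissue median TPM >= 1 everywhere and < 2-fold spread."""
    med = _median_tpm_by_tissue(matrix)
    lo, hi = med.min(axis=0), med.max(axis=0)
    mask = (lo >= 1.0) & (hi / np.maximum(lo, 1e-300) < 2.0)
    return set(med.columns[mask])


def tissue_specific_genes(matrix, fold_threshold=5.0, min_tpm=1.0) -> dict:
    """Tissue-enhanced genes per tissue under the fold-over-others surrogate rule."""
    med = _median_tpm_by_tissue(matrix)
    out = {}
    for t in med.index:
        own = med.loc[t]
        others = med.drop(index=t).mean(axis=0)
        mask = (own >= min_tpm) & (own >= fold_threshold * others)
        out[t] = set(med.columns[mask])
    return out


@dataclass
class DEResult:
    table: pd.DataFrame  # per gene: U, p, fdr, fold, direction, passed
    fdr_threshold: float
    fold_threshold: float

    @property
    def passing(self) -> set:
        return set(self.table.index[self.table["passed"]])


def differential_expression(normal, cancer, fdr_threshold=0.001, fold_threshold=3.0) -> DEResult:
    """Per-gene two-sided Mann-Whitney U with BH-FDR and median-fold filter.

    ``normal``/``cancer`` are ExpressionMatrix slices over the same genes.
    Fold change = max(median TPM) / min(median TPM) across the two groups
    with pseudocount 0.01; direction records which group is higher.
    """
    if normal.n_samples < 3 or cancer.n_samples < 3:
        raise ValueError("each group needs at least 3 samples")
    if list(normal.gene_ids) != list(cancer.gene_ids):
        raise ValueError("gene universes differ")
    xn, xc = normal.values, cancer.values
    u, p = sps.mannwhitneyu(xc, xn, alternative="two-sided", axis=0)
    fdr = multipletests(p, method="fdr_bh")[1]
    mn = np.median(normal.tpm(), axis=0) + PSEUDOCOUNT
    mc = np.median(cancer.tpm(), axis=0) + PSEUDOCOUNT
    fold = np.maximum(mn, mc) / np.minimum(mn, mc)
    direction = np.where(mc >= mn, "up", "down")
    passed = (fdr <= fdr_threshold) & (fold >= fold_threshold)
    table = pd.DataFrame(
        {"U": u, "p": p, "fdr": fdr, "fold": fold, "direction": direction, "passed": passed},
        index=list(normal.gene_ids),
    )
    return DEResult(table=table, fdr_threshold=fdr_threshold, fold_threshold=fold_threshold)


def enrichment_fold(gene_set, annotation, universe):
    """(observed, expected, fold) of an annotation within a gene set.

    expected = |gene_set| * |annotation| / |universe|; fold is None when the
    expectation is zero.
    """
    gene_set, annotation, universe = set(gene_set), set(annotation), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe or not annotation <= universe:
        raise ValueError("sets must be subsets of the universe")
    observed = len(gene_set & annotation)
    expected = len(gene_set) * len(annotation) / len(universe)
    fold = observed / expected if expected > 0 else None
    return observed, expected, fold


def shared_top_genes(per_sample_top, group_labels, min_samples=2) -> dict:
    """Genes in the top-k of >= min_samples samples of the same group."""
    if len(per_sample_top) != len(group_labels):
        raise ValueError("one group label per sample required")
    out = {}
    for g in sorted(set(group_labels)):
        counts = Counter()
        for top, lab in zip(per_sample_top, group_labels):
            if lab == g:
                counts.update(set(top))
        out[g] = {gene for gene, c in counts.items() if c >= min_samples}
    return out


def expression_overlap_report(top_lists: dict, matrix, ts_sets=None, hk_set=None, k=100,
                              score_vectors: dict | None = None) -> pd.DataFrame:
    """Overlaps of top contributing genes with expression-derived gene sets.

    ``top_lists`` maps (tissue, label) -> ranked top-k gene list.  For each
    entry the overlap with the tissue's top-k *expressed* genes (by median
    TPM), with its TS set and with the HK set is reported; when
    ``score_vectors`` provides the raw per-gene scores, Spearman between
    scores and the tissue median expression is added.
    """
    med = _median_tpm_by_tissue(matrix)
    ts_sets = ts_sets or {}
    hk_set = hk_set or set()
    rows = []
    for (tissue, label), top in top_lists.items():
        top = set(list(top)[:k])
        top_expr = set(rank_genes(med.loc[tissue].to_numpy(), med.columns.to_numpy())[:k])
        row = {
            "tissue": tissue,
            "config": label,
            "overlap_top_expressed": len(top & top_expr) / k,
            "overlap_ts": len(top & ts_sets.get(tissue, set())) / k,
            "overlap_hk": len(top & hk_set) / k,
        }
        if score_vectors and (tissue, label) in score_vectors:
            row["spearman_score_vs_expression"] = spearman(
                score_vectors[(tissue, label)], med.loc[tissue].to_numpy()
            )
        rows.append(row)
    return pd.DataFrame(rows)


def marker_recall(top_genes, marker_set) -> float:
    """Fraction of planted markers recovered in a top-k list."""
    marker_set = set(marker_set)
    if not marker_set:
        raise ValueError("empty marker set")
    return len(set(top_genes) & marker_set) / len(marker_set)
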