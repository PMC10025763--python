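"""Synthetic transcriptome cohorts with planted ground truth.

Cohorts emulate the structure of large bulk RNA-seq compendia on the
log2(TPM+1) scale: several tissue classes, tissue-enhanced marker genes,
housekeeping (HK) genes with stable expression across tissues, and optional
paired cancer classes carrying planted differential-expression (DE) effects.

Generative model
----------------
Each gene g has a background level ``b_g`` on the log2(TPM+1) scale drawn
from a normal distribution (``bg_log2_mean``, ``bg_log2_sd``) truncated at 0,
i.e. a right-skewed log-normal-like TPM background.  Marker genes add
``log2(marker_effect)`` in their tissue only, so the fold change is applied
multiplicatively on the TPM+1 scale and the per-tissue median log2 difference
equals log2(marker_effect) exactly in the noise-free case.  HK genes are
fixed at ``log2(hk_level+1)`` in every class.  Cancer classes copy their
normal tissue and shift planted DE genes by ±log2(de_effect); DE genes are
drawn from the highest-baseline background genes so the realized TPM-scale
fold stays close to nominal.  i.i.d. Gaussian noise (sd ``noise_sd``) is
added on the log2 scale and values are clipped at 0.

Seeding is hierarchical off the single design seed, so cohorts are
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd


@dataclass
class SyntheticDesign:
    n_tissues: int = 4
    n_samples_per_tissue: int | list = 50
    n_genes: int = 1000
    n_markers_per_tissue: int = 25
    marker_effect: float = 4.0
    n_hk_genes: int = 50
    hk_level: float = 50.0
    noise_sd: float = 0.3
    cancer_fraction: float = 0.5
    n_de_genes_per_cancer: int = 30
    de_effect: float = 4.0
    bg_log2_mean: float = 3.5
    bg_log2_sd: float = 1.5
    seed: int = 0

    def samples_per_tissue(self):
        if isinstance(self.n_samples_per_tissue, int):
            return [self.n_samples_per_tissue] * self.n_tissues
        counts = list(self.n_samples_per_tissue)
        if len(counts) != self.n_tissues:
            raise ValueError("per-tissue sample counts must match n_tissues")
        return counts

    def validate(self):
        if self.n_tissues < 2:
            raise ValueError("need at least 2 tissues")
        if self.marker_effect <= 1:
            raise ValueError("marker_effect must be > 1")
        if self.de_effect < 1:
            raise ValueError("de_effect must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        n_cancers = int(round(self.cancer_fraction * self.n_tissues))
        budget = (
            self.n_markers_per_tissue * self.n_tissues
            + self.n_hk_genes
            + n_cancers * self.n_de_genes_per_cancer
        )
        if budget > self.n_genes:
            raise ValueError(
                f"gene budget exceeded: {budget} planted genes for {self.n_genes} total"
            )


@dataclass
class ExpressionMatrix:
    """Samples x genes of log2(TPM+1) values with sample/gene IDs and tissue labels."""

    values: np.ndarray
    gene_ids: list
    sample_ids: list
    tissue_labels: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("matrix shape does not match id lists")
        if len(self.tissue_labels) != len(self.sample_ids):
            raise ValueError("one tissue label per sample required")
        if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
            raise ValueError("expression values must be finite and >= 0")

    @property
    def n_samples(self):
        return self.values.shape[0]

    @property
    def n_genes(self):
        return self.values.shape[1]

    @property
    def tissues(self):
        return sorted(set(self.tissue_labels))

    def subset(self, idx):
        idx = np.asarray(idx)
        return ExpressionMatrix(
            values=self.values[idx],
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            tissue_labels=[self.tissue_labels[i] for i in idx],
        )

    def samples_of(self, tissue):
        return np.flatnonzero(np.asarray(self.tissue_labels) == tissue)

    def tpm(self):
        """Back-transform to the TPM scale."""
        return 2.0**self.values - 1.0

    def to_frame(self):
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class GroundTruth:
    markers: dict = field(default_factory=dict)  # tissue -> set of gene ids
    hk_genes: set = field(default_factory=set)
    de_genes: dict = field(default_factory=dict)  # cancer class -> list of (gene, direction, fold)

    def to_json(self):
        return json.dumps(
            {
                "markers": {t: sorted(s) for t, s in self.markers.items()},
                "hk_genes": sorted(self.hk_genes),
                "de_genes": {c: [[g, d, f] for g, d, f in v] for c, v in self.de_genes.items()},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text):
        d = json.loads(text)
        return cls(
            markers={t: set(s) for t, s in d["markers"].items()},
            hk_genes=set(d["hk_genes"]),
            de_genes={c: [(g, d_, f) for g, d_, f in v] for c, v in d["de_genes"].items()},
        )


def generate_cohort(design: SyntheticDesign):
    """Generate an (ExpressionMatrix, GroundTruth) pair from a design."""
    design.validate()
    root = np.random.SeedSequence(design.seed)
    rng_assign, rng_bg, rng_noise = [np.random.default_rng(s) for s in root.spawn(3)]

    n_genes = design.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    tissues = [f"tissue{t}" for t in range(design.n_tissues)]
    counts = design.samples_per_tissue()

    # background level per gene on log2(TPM+1) scale, clipped at 0 (right-skewed TPM)
    baseline = np.maximum(rng_bg.normal(design.bg_log2_mean, design.bg_log2_sd, size=n_genes), 0.0)

    # assign planted roles on disjoint gene blocks (random positions)
    perm = rng_assign.permutation(n_genes)
    pos = 0
    markers = {}
    for t in tissues:
        markers[t] = perm[pos : pos + design.n_markers_per_tissue]
        pos += design.n_markers_per_tissue
    hk_idx = perm[pos : pos + design.n_hk_genes]
    pos += design.n_hk_genes
    baseline[hk_idx] = np.log2(design.hk_level + 1.0)

    n_cancers = int(round(design.cancer_fraction * design.n_tissues))
    cancer_tissues = tissues[:n_cancers]

    # DE genes: highest-baseline unplanted genes, so the realized TPM fold
    # change tracks the nominal effect (see methods note)
    free = perm[pos:]
    free_sorted = free[np.argsort(-baseline[free], kind="stable")]
    de_assign = {}
    fpos = 0
    for t in cancer_tissues:
        de_assign[t] = free_sorted[fpos : fpos + design.n_de_genes_per_cancer]
        fpos += design.n_de_genes_per_cancer

    # per-class mean profiles on the log2 scale
    class_profiles = {}
    for t in tissues:
        prof = baseline.copy()
        prof[markers[t]] += np.log2(design.marker_effect)
        prof[hk_idx] = np.log2(design.hk_level + 1.0)
        class_profiles[t] = prof

    gt = GroundTruth(
        markers={t: {gene_ids[i] for i in markers[t]} for t in tissues},
        hk_genes={gene_ids[i] for i in hk_idx},
    )
    for t in cancer_tissues:
        cname = f"{t}_cancer"
        prof = class_profiles[t].copy()
        directions = rng_assign.choice([1, -1], size=len(de_assign[t]))
        # plant the fold exactly on the TPM scale so the realized median-TPM
        # ratio is unbiased (markers instead use the log2-additive form)
        tpm_n = 2.0 ** prof[de_assign[t]] - 1.0
        tpm_c = np.where(directions > 0, tpm_n * design.de_effect, tpm_n / design.de_effect)
        prof[de_assign[t]] = np.log2(tpm_c + 1.0)
        class_profiles[cname] = prof
        gt.de_genes[cname] = [
            (gene_ids[i], "up" if d > 0 else "down", design.de_effect)
            for i, d in zip(de_assign[t], directions)
        ]

    class_list = tissues + [f"{t}_cancer" for t in cancer_tissues]
    class_counts = counts + [counts[tissues.index(t)] for t in cancer_tissues]

    rows, sample_ids, labels = [], [], []
    for cls, n in zip(class_list, class_counts):
        noise = rng_noise.normal(0.0, design.noise_sd, size=(n, n_genes)) if design.noise_sd > 0 else 0.0
        block = np.maximum(class_profiles[cls][None, :] + noise, 0.0)
        rows.append(np.broadcast_to(block, (n, n_genes)) if np.isscalar(noise) else block)
        sample_ids.extend(f"{cls}_s{j:03d}" for j in range(n))
        labels.extend([cls] * n)

    matrix = ExpressionMatrix(
        values=np.vstack(rows),
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        tissue_labels=labels,
    )
    return matrix, gt


def split_train_test(matrix: ExpressionMatrix, ratio: float, seed: int):
    """Stratified-per-tissue split into (train, test); e.g. ratio=0.9 gives 9:1."""
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    labels = np.asarray(matrix.tissue_labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for t in matrix.tissues:
        idx = np.flatnonzero(labels == t)
        if len(idx) < 2:
            raise ValueError(f"class {t!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        n_train = int(round(ratio * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return matrix.subset(sorted(train_idx)), matrix.subset(sorted(test_idx))


def design_to_dict(design: SyntheticDesign) -> dict:
    return asdict(design)
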