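"""Readers and writers for the package's plain-text formats.

Expression matrices are TSV with gene IDs in the first column and sample IDs
as the header row (genes x samples on disk, the common convention for
expression tables), with a two-column sidecar TSV mapping sample ID to
tissue label.  Attribution vectors are two-column TSV (gene_id, score).
Gene lists are one symbol per line.  Ground truth and reports are JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .syndata import ExpressionMatrix, GroundTruth


def write_matrix(matrix: ExpressionMatrix, path, labels_path=None):
    path = Path(path)
    frame = pd.DataFrame(matrix.values.T, index=matrix.gene_ids, columns=matrix.sample_ids)
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")
    labels_path = Path(labels_path) if labels_path else path.with_suffix(".labels.tsv")
    pd.DataFrame({"sample_id": matrix.sample_ids, "tissue": matrix.tissue_labels}).to_csv(
        labels_path, sep="\t", index=False
    )
    return path, labels_path


def read_matrix(path, labels_path=None) -> ExpressionMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    labels_path = Path(labels_path) if labels_path else path.with_suffix(".labels.tsv")
    lab = pd.read_csv(labels_path, sep="\t")
    labels = dict(zip(lab["sample_id"], lab["tissue"]))
    missing = [s for s in frame.columns if s not in labels]
    if missing:
        raise ValueError(f"samples without tissue label: {missing[:5]}")
    return ExpressionMatrix(
        values=frame.to_numpy().T,
        gene_ids=list(frame.index),
        sample_ids=list(frame.columns),
        tissue_labels=[labels[s] for s in frame.columns],
    )


def write_ground_truth(gt: GroundTruth, path):
    Path(path).write_text(gt.to_json())


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def write_attribution(gene_ids, scores, path, meta=None):
    path = Path(path)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("attribution scores must be finite")
    pd.DataFrame({"gene_id": gene_ids, "score": scores}).to_csv(path, sep="\t", index=False)
    if meta is not None:
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1, default=str))
    return path


def read_attribution(path):
    frame = pd.read_csv(path, sep="\t")
    if set(frame.columns) != {"gene_id", "score"}:
        raise ValueError(f"malformed attribution file {path}: columns {list(frame.columns)}")
    scores = frame["score"].to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        bad = int(np.flatnonzero(~np.isfinite(scores))[0]) + 2  # 1-based + header
        raise ValueError(f"non-finite score at line {bad} of {path}")
    return list(frame["gene_id"]), scores


def read_gene_list(path) -> list:
    """One gene symbol per line; duplicates are dropped with a warning."""
    seen, out, dups = set(), [], 0
    for line in Path(path).read_text().splitlines():
        g = line.strip()
        if not g or g.startswith("#"):
            continue
        if g in seen:
            dups += 1
            continue
        seen.add(g)
        out.append(g)
    if dups:
        warnings.warn(f"{dups} duplicate gene symbols dropped from {path}")
    return out


def write_report(obj, path):
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    return str(o)
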