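"""Baseline references for difference-from-reference explainers.

Four reference kinds are supported for DeepLift, DeepLiftShap and
IntegratedGradients, all on the log2(TPM+1) scale:

* ``zero``      — the all-zero transcriptome (the "black image").
* ``normal``    — i.i.d. truncated N(0, 1) restricted to [0, 1] per gene
  (the "random pixel values").
* ``universal`` — per-gene truncated N(mu_g, sigma_g) with the moments taken
  over samples from *all* tissues.
* ``specific``  — as universal, but moments taken over one tissue's samples.

For universal/specific the truncation interval is configurable: the
``paper_literal`` mode restricts values to [0, sigma]; the default
``symmetric`` mode uses [max(0, mu - sigma), mu + sigma], which keeps
references near realistic expression levels.  Degenerate genes
(sigma = 0) emit mu clamped into the interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ReferenceSpec:
    kind: str  # zero | normal | universal | specific
    pool_size: int = 2000
    tissue: str | None = None
    seed: int = 0
    bound_mode: str = "symmetric"  # or "paper_literal"

    def __post_init__(self):
        if self.kind not in ("zero", "normal", "universal", "specific"):
            raise ValueError(f"unknown reference kind {self.kind!r}")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if (self.tissue is not None) != (self.kind == "specific"):
            raise ValueError("tissue must be given exactly when kind='specific'")
        if self.bound_mode not in ("symmetric", "paper_literal"):
            raise ValueError(f"unknown bound_mode {self.bound_mode!r}")

    def descriptor(self):
        t = f",tissue={self.tissue}" if self.tissue else ""
        return f"{self.kind}(pool={self.pool_size},bounds={self.bound_mode}{t})"


@dataclass
class GeneStats:
    mu: np.ndarray
    sigma: np.ndarray
    scope: str  # "all" or the tissue label

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma < 0) or not np.all(np.isfinite(self.mu)):
            raise ValueError("invalid gene statistics")


def gene_stats(matrix, tissue=None) -> GeneStats:
    """Per-gene mean and sample (n-1) standard deviation of log2(TPM+1)."""
    if tissue is None:
        vals = matrix.values
        scope = "all"
    else:
        idx = matrix.samples_of(tissue)
        if len(idx) == 0:
            raise ValueError(f"unknown tissue {tissue!r}")
        vals = matrix.values[idx]
        scope = tissue
    ddof = 1 if vals.shape[0] > 1 else 0
    return GeneStats(mu=vals.mean(axis=0), sigma=vals.std(axis=0, ddof=ddof), scope=scope)


def _truncation_interval(spec: ReferenceSpec, stats: GeneStats):
    if spec.bound_mode == "paper_literal":
        lo = np.zeros_like(stats.mu)
        hi = stats.sigma.copy()
    else:
        lo = np.maximum(stats.mu - stats.sigma, 0.0)
        hi = stats.mu + stats.sigma
    return lo, hi

def _truncnorm_draws(mu, sigma, lo, hi, size, rng):
    """Vectorized truncated-normal sampling via the analytic CDF inverse."""
    out = np.empty(size)
    degenerate = (sigma <= 0) | (hi <= lo)
    ok = ~degenerate
    if np.any(ok):
        a = (lo[ok] - mu[ok]) / sigma[ok]
        b = (hi[ok] - mu[ok]) / sigma[ok]
        draws = stats.truncnorm.rvs(a, b, loc=mu[ok], scale=sigma[ok], size=(size[0], ok.sum()), random_state=rng)
        out[:, ok] = draws
    if np.any(degenerate):
        out[:, degenerate] = np.clip(mu[degenerate], lo[degenerate], hi[degenerate])
    return out


def make_reference(spec: ReferenceSpec, gstats: GeneStats | None = None, n_genes: int | None = None, rng=None):
    """A single reference vector (see :func:`build_reference_pool` for pools)."""
    return build_reference_pool(spec, gstats, n_genes=n_genes, pool_size=1, rng=rng)[0]


def build_reference_pool(spec: ReferenceSpec, gstats: GeneStats | None = None, n_genes=None, pool_size=None, rng=None):
    """Pool of reference vectors, shape (pool_size, n_genes); seeded by spec.seed."""
    pool_size = pool_size if pool_size is not None else spec.pool_size
    if spec.kind in ("universal", "specific"):
        if gstats is None:
            raise ValueError(f"reference kind {spec.kind!r} requires gene statistics")
        n_genes = len(gstats.mu)
    elif n_genes is None:
        if gstats is None:
            raise ValueError("n_genes required for zero/normal references")
        n_genes = len(gstats.mu)
    rng = rng if rng is not None else np.random.default_rng(spec.seed)

    if spec.kind == "zero":
        return np.zeros((pool_size, n_genes))
    if spec.kind == "normal":
        a, b = 0.0, 1.0  # N(0,1) truncated to [0,1] -> standardized bounds are 0 and 1
        return stats.truncnorm.rvs(a, b, loc=0.0, scale=1.0, size=(pool_size, n_genes), random_state=rng)
    lo, hi = _truncation_interval(spec, gstats)
    return _truncnorm_draws(gstats.mu, gstats.sigma, lo, hi, (pool_size, n_genes), rng)


def draw_references(pool: np.ndarray, n: int, rng) -> np.ndarray:
    """Draw n references without replacement from a pool."""
    pool = np.atleast_2d(pool)
    if not (1 <= n <= pool.shape[0]):
        raise ValueError("need 1 <= n <= pool size")
    idx = rng.choice(pool.shape[0], size=n, replace=False)
    return pool[idx]


def truncnorm_mean(mu, sigma, lo, hi):
    """Analytic mean of N(mu, sigma) truncated to [lo, hi] (test oracle helper)."""
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.mean(a, b, loc=mu, scale=sigma)
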