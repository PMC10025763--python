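"""Minimal reverse-mode neural-network engine for expression classifiers.

The attribution methods in :mod:`genexplain.explainers` need three distinct
backward passes through the same network:

* plain gradients (``backward`` with ``guided=False``),
* guided backpropagation (ReLUs additionally zero negative incoming signal),
* DeepLIFT Rescale multipliers (``deeplift_multipliers``), which require the
  cached forward activations of *two* passes (sample and reference).

No general autodiff framework exposes all three uniformly, so the layers here
implement each rule explicitly.  Layers are batch-first; dense inputs are
``(N, features)``, convolutional inputs ``(N, C, H, W)``.

Dropout semantics: during training each sample draws its own mask; during
explanation one mask per call is drawn and shared across the batch, so a call
corresponds to a single thinned architecture (masks are recorded on the first
forward pass and replayed on the reference pass so DeepLIFT sees the same
subnetwork twice).
"""

from __future__ import annotations

from collections import deque
from typing import Sequence

import numpy as np

_DL_EPS = 1e-7  # |delta input| below which the Rescale rule falls back to the gradient


class Context:
    """Per-forward-pass options threaded through the layers.

    ``record_masks``/``replay_masks`` carry dropout masks between the sample
    and reference passes of DeepLIFT.
    """

    def __init__(self, train=False, rng=None, record_masks=None, replay_masks=None):
        self.train = train
        self.rng = rng
        self.record_masks = record_masks
        self.replay_masks = deque(replay_masks) if replay_masks is not None else None


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, ctx):  # -> (y, cache)
        raise NotImplementedError

    def backward(self, g, cache, guided=False, want_param_grads=False):
        raise NotImplementedError

    def deeplift(self, m, cache_x, cache_ref):
        """Propagate DeepLIFT multipliers from output to input."""
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, d_in, d_out, rng):
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(d_in, d_out)),
            "b": np.zeros(d_out),
        }

    def forward(self, x, ctx):
        return x @ self.params["W"] + self.params["b"], x

    def backward(self, g, cache, guided=False, want_param_grads=False):
        if want_param_grads:
            self.grads["W"] = cache.T @ g
            self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"].T

    def deeplift(self, m, cache_x, cache_ref):
        # affine stage: multipliers propagate exactly like gradients
        return m @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, ctx):
        return np.maximum(x, 0.0), x

    def backward(self, g, cache, guided=False, want_param_grads=False):
        g = g * (cache > 0)
        if guided:
            g = g * (g > 0)
        return g

    def deeplift(self, m, cache_x, cache_ref):
        dx = cache_x - cache_ref
        dy = np.maximum(cache_x, 0.0) - np.maximum(cache_ref, 0.0)
        grad_fallback = (cache_x > 0).astype(float)
        safe = np.abs(dx) >= _DL_EPS
        ratio = np.where(safe, dy / np.where(safe, dx, 1.0), grad_fallback)
        return m * ratio


class BatchNorm(Layer):
    """Batch normalization over the batch axis (dense) or batch+spatial (conv)."""

    def __init__(self, n_features, conv=False, eps=1e-5, momentum=0.1):
        super().__init__()
        self.conv = conv
        self.eps = eps
        self.momentum = momentum
        self.params = {"gamma": np.ones(n_features), "beta": np.zeros(n_features)}
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def _shape(self, v):
        return v.reshape(1, -1, 1, 1) if self.conv else v.reshape(1, -1)

    def forward(self, x, ctx):
        axes = (0, 2, 3) if self.conv else (0,)
        if ctx.train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // x.shape[1]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            unbiased = var * n / max(n - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(mean)) * self._shape(invstd)
        y = self._shape(self.params["gamma"]) * xhat + self._shape(self.params["beta"])
        return y, (xhat, invstd, ctx.train)

    def backward(self, g, cache, guided=False, want_param_grads=False):
        xhat, invstd, was_train = cache
        axes = (0, 2, 3) if self.conv else (0,)
        if want_param_grads:
            self.grads["gamma"] = (g * xhat).sum(axis=axes)
            self.grads["beta"] = g.sum(axis=axes)
        gxhat = g * self._shape(self.params["gamma"])
        if not was_train:
            return gxhat * self._shape(invstd)
        n = g.size // g.shape[1]
        mean_g = gxhat.mean(axis=axes)
        mean_gx = (gxhat * xhat).mean(axis=axes)
        return self._shape(invstd) * (gxhat - self._shape(mean_g) - xhat * self._shape(mean_gx))

    def deeplift(self, m, cache_x, cache_ref):
        # evaluation mode: a per-feature affine map
        _, invstd, was_train = cache_x
        if was_train:
            raise RuntimeError("DeepLIFT requires batch norm in evaluation mode")
        return m * self._shape(self.params["gamma"]) * self._shape(invstd)


class Dropout(Layer):
    def __init__(self, p):
        super().__init__()
        self.p = p

    def forward(self, x, ctx):
        if self.p <= 0:
            return x, None
        if ctx.replay_masks:
            mask = ctx.replay_masks.popleft()
        elif ctx.train and ctx.rng is not None:
            mask = (ctx.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        elif ctx.rng is not None:
            # explanation mode: one mask per call, shared across the batch
            mask = (ctx.rng.random(x.shape[1:]) >= self.p) / (1.0 - self.p)
        else:
            return x, None
        if ctx.record_masks is not None:
            ctx.record_masks.append(mask)
        return x * mask, mask

    def backward(self, g, cache, guided=False, want_param_grads=False):
        return g if cache is None else g * cache

    def deeplift(self, m, cache_x, cache_ref):
        return m if cache_x is None else m * cache_x


class Conv2d(Layer):
    """Stride-1 'same' convolution (odd kernels)."""

    def __init__(self, c_in, c_out, kernel, rng):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("only odd kernel sizes are supported")
        self.kernel = kernel
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.params = {
            "W": rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)),
            "b": np.zeros(c_out),
        }

    def _pad(self, x):
        p = self.kernel // 2
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))

    def forward(self, x, ctx):
        xp = self._pad(x)
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.kernel, self.kernel), axis=(2, 3))
        y = np.einsum("nchwij,ocij->nohw", win, self.params["W"], optimize=True)
        y += self.params["b"].reshape(1, -1, 1, 1)
        return y, (x.shape, win)

    def backward(self, g, cache, guided=False, want_param_grads=False):
        x_shape, win = cache
        k, p = self.kernel, self.kernel // 2
        if want_param_grads:
            self.grads["W"] = np.einsum("nohw,nchwij->ocij", g, win, optimize=True)
            self.grads["b"] = g.sum(axis=(0, 2, 3))
        n, _, h, w = x_shape
        gxp = np.zeros((n, win.shape[1], h + 2 * p, w + 2 * p))
        gcols = np.einsum("nohw,ocij->ncijhw", g, self.params["W"], optimize=True)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + h, j : j + w] += gcols[:, :, i, j]
        return gxp[:, :, p : p + h, p : p + w]

    def deeplift(self, m, cache_x, cache_ref):
        return self.backward(m, cache_x)


class MaxPool2d(Layer):
    """Non-overlapping max pooling; trailing rows/cols that do not fill a window are dropped."""

    def __init__(self, kernel=2):
        super().__init__()
        self.k = kernel

    def _windows(self, x):
        n, c, h, w = x.shape
        h2, w2 = h // self.k, w // self.k
        xc = x[:, :, : h2 * self.k, : w2 * self.k]
        r = xc.reshape(n, c, h2, self.k, w2, self.k)
        return r.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, self.k * self.k)

    def forward(self, x, ctx):
        win = self._windows(x)
        idx = win.argmax(axis=-1)
        y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        return y, (x, idx, y)

    def _scatter(self, vals, idx, x_shape):
        n, c, h, w = x_shape
        h2, w2 = h // self.k, w // self.k
        flat = np.zeros((n, c, h2, w2, self.k * self.k))
        np.put_along_axis(flat, idx[..., None], vals[..., None], axis=-1)
        out = np.zeros(x_shape)
        out[:, :, : h2 * self.k, : w2 * self.k] = (
            flat.reshape(n, c, h2, w2, self.k, self.k).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 * self.k, w2 * self.k)
        )
        return out

    def backward(self, g, cache, guided=False, want_param_grads=False):
        x, idx, _ = cache
        return self._scatter(g, idx, x.shape)

    def deeplift(self, m, cache_x, cache_ref):
        # Route multipliers to the sample-pass argmax cell, rescaled so that
        # m_in * (x_p - ref_p) = m_out * (max(x) - max(ref)); gradient
        # fallback (ratio 1) when the selected input delta is tiny.
        x, idx, y_x = cache_x
        ref, _, y_ref = cache_ref
        dy = y_x - y_ref
        dwin = self._windows(x - ref)
        dsel = np.take_along_axis(dwin, np.broadcast_to(idx, dwin.shape[:-1])[..., None], axis=-1)[..., 0]
        b = np.broadcast_shapes(m.shape, dy.shape, dsel.shape)
        m = np.broadcast_to(m, b)
        dy = np.broadcast_to(dy, b)
        dsel = np.broadcast_to(dsel, b)
        safe = np.abs(dsel) >= _DL_EPS
        vals = np.where(safe, m * dy / np.where(safe, dsel, 1.0), m)
        idx_b = np.broadcast_to(idx, b)
        return self._scatter(vals, idx_b, (b[0],) + x.shape[1:])


class GlobalAvgPool(Layer):
    def forward(self, x, ctx):
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, g, cache, guided=False, want_param_grads=False):
        n, c, h, w = cache
        return np.broadcast_to(g[:, :, None, None] / (h * w), (g.shape[0], c, h, w)).copy()

    def deeplift(self, m, cache_x, cache_ref):
        shape = cache_x
        return self.backward(m, (m.shape[0],) + shape[1:])


class GridReshape(Layer):
    """Place a gene-expression vector row-major into a square grid.

    Cell ``k`` of the flattened grid holds gene ``gene_order[k]``; trailing
    cells are zero padding.  The backward/multiplier pass gathers grid values
    back to gene order, discarding pad cells (their total is kept in
    ``last_pad_attribution`` for auditing).
    """

    def __init__(self, gene_order, side):
        super().__init__()
        self.gene_order = np.asarray(gene_order)
        self.side = side
        self.n_genes = len(self.gene_order)
        if side * side < self.n_genes:
            raise ValueError("grid side too small for gene count")
        self.last_pad_attribution = 0.0

    def forward(self, x, ctx):
        n = x.shape[0]
        flat = np.zeros((n, self.side * self.side))
        flat[:, : self.n_genes] = x[:, self.gene_order]
        return flat.reshape(n, 1, self.side, self.side), None

    def _gather(self, g):
        flat = g.reshape(g.shape[0], -1)
        self.last_pad_attribution = float(np.abs(flat[:, self.n_genes :]).sum())
        out = np.zeros((g.shape[0], self.n_genes))
        out[:, self.gene_order] = flat[:, : self.n_genes]
        return out

    def backward(self, g, cache, guided=False, want_param_grads=False):
        return self._gather(g)

    def deeplift(self, m, cache_x, cache_ref):
        return self._gather(m)

    def cell_of_gene(self):
        """Map gene index -> flat grid cell index."""
        cell = np.empty(self.n_genes, dtype=int)
        cell[self.gene_order] = np.arange(self.n_genes)
        return cell


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x, ctx=None):
        ctx = ctx or Context()
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x, ctx)
            caches.append(c)
        return x, caches

    def backward(self, g_out, caches, guided=False, want_param_grads=False, stop_at=0):
        g = g_out
        for i in range(len(self.layers) - 1, stop_at - 1, -1):
            g = self.layers[i].backward(g, caches[i], guided=guided, want_param_grads=want_param_grads)
        return g

    def deeplift_multipliers(self, m_out, caches_x, caches_ref):
        m = m_out
        for layer, cx, cr in zip(reversed(self.layers), reversed(caches_x), reversed(caches_ref)):
            m = layer.deeplift(m, cx, cr)
        return m

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield (i, name), layer, value


class Adam:
    def __init__(self, net: Sequential, lr, l2_lambda=0.0, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr = lr
        self.l2 = l2_lambda
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {}
        self.v = {}
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, layer, value in self.net.parameters():
            g = layer.grads.get(key[1])
            if g is None:
                continue
            if self.l2 > 0 and key[1] == "W":
                g = g + self.l2 * value
            m = self.m.setdefault(key, np.zeros_like(value))
            v = self.v.setdefault(key, np.zeros_like(value))
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
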