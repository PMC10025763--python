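"""Per-gene attribution methods for trained expression classifiers.

Eight backprop-based explainers are implemented against the engine in
:mod:`genexplain.nn`:

==================  ==========================================================
Saliency            absolute gradient of the target class score (signed
                    variant behind ``signed=True``)
InputXGradient      gradient * input, elementwise
GuidedBackprop      gradient with the guided-ReLU rule (backward signal also
                    zeroed where negative)
IntegratedGradients midpoint-rule path integral of gradients from a reference
DeepLift            Rescale-rule difference-from-reference contributions
DeepLiftShap        DeepLift averaged over references drawn from a pool
GuidedGradCam       Grad-CAM map (CNN only) * guided backprop
GuidedGradCam++     Grad-CAM++ map (CNN only) * guided backprop
==================  ==========================================================

All methods target the *pre-softmax* class score.  When dropout is enabled a
single mask per call is drawn from the seed and shared by every forward /
backward pass inside the call, so one call sees one thinned architecture —
repeated calls with fresh seeds are the source of intra-model variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .models import TrainedClassifier

MLP_EXPLAINERS = (
    "Saliency",
    "InputXGradient",
    "GuidedBackprop",
    "IntegratedGradients",
    "DeepLift",
    "DeepLiftShap",
)
CNN_ONLY_EXPLAINERS = ("GuidedGradCam", "GuidedGradCam++")
ALL_EXPLAINERS = MLP_EXPLAINERS + CNN_ONLY_EXPLAINERS

REFERENCE_EXPLAINERS = ("IntegratedGradients", "DeepLift", "DeepLiftShap")


@dataclass
class AttributionVector:
    scores: np.ndarray
    explainer_id: str
    sample_id: str = ""
    model_id: str = ""
    replicate_id: int = 0
    target_class: object = None
    reference_descriptor: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("attribution scores must be finite")


def _target_index(model: TrainedClassifier, target_class):
    if isinstance(target_class, (int, np.integer)):
        return int(target_class)
    return model.class_index(target_class)


def _dropout_rng(dropout_enabled, seed):
    return np.random.default_rng(seed) if dropout_enabled else None


def _grad(model, X, t, rng=None, guided=False, record_masks=None, replay_masks=None):
    z, caches = model.logits(X, dropout_rng=rng, record_masks=record_masks, replay_masks=replay_masks)
    g_out = np.zeros_like(z)
    g_out[:, t] = 1.0
    return model.net.backward(g_out, caches, guided=guided), z[:, t]


def saliency(model, sample, target_class, dropout_enabled=False, seed=None, signed=False):
    t = _target_index(model, target_class)
    g, _ = _grad(model, np.atleast_2d(sample), t, rng=_dropout_rng(dropout_enabled, seed))
    return g[0] if signed else np.abs(g[0])


def input_x_gradient(model, sample, target_class, dropout_enabled=False, seed=None):
    sample = np.asarray(sample, dtype=float)
    t = _target_index(model, target_class)
    g, _ = _grad(model, sample.reshape(1, -1), t, rng=_dropout_rng(dropout_enabled, seed))
    return g[0] * sample


def guided_backprop(model, sample, target_class, dropout_enabled=False, seed=None):
    t = _target_index(model, target_class)
    g, _ = _grad(model, np.atleast_2d(sample), t, rng=_dropout_rng(dropout_enabled, seed), guided=True)
    return g[0]


def integrated_gradients(model, sample, reference, target_class, n_steps=50, dropout_enabled=False, seed=None):
    """Midpoint-rule approximation of the path integral from reference to sample."""
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if sample.shape != reference.shape:
        raise ValueError("sample and reference must have the same length")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    t = _target_index(model, target_class)
    alphas = (np.arange(1, n_steps + 1) - 0.5) / n_steps
    points = reference[None, :] + alphas[:, None] * (sample - reference)[None, :]
    rng = _dropout_rng(dropout_enabled, seed)
    grads, _ = _grad(model, points, t, rng=rng)
    return (sample - reference) * grads.mean(axis=0)


def deeplift(model, sample, reference, target_class, dropout_enabled=False, seed=None):
    """DeepLIFT Rescale-rule contributions against a single reference.

    ``reference`` may also be a ``(R, n_genes)`` batch, in which case an
    ``(R, n_genes)`` matrix of contributions is returned (used by
    DeepLiftShap).
    """
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    single = reference.ndim == 1
    refs = np.atleast_2d(reference)
    if refs.shape[1] != sample.shape[-1]:
        raise ValueError("sample and reference must have the same length")
    t = _target_index(model, target_class)
    rng = _dropout_rng(dropout_enabled, seed)
    masks = []
    _, caches_x = model.logits(sample, dropout_rng=rng, record_masks=masks)
    _, caches_r = model.logits(refs, replay_masks=masks)
    m_out = np.zeros((refs.shape[0], model.n_classes))
    m_out[:, t] = 1.0
    m_in = model.net.deeplift_multipliers(m_out, caches_x, caches_r)
    contribs = m_in * (sample.reshape(1, -1) - refs)
    return contribs[0] if single else contribs


def deeplift_shap(model, sample, reference_pool, target_class, n_references=1, dropout_enabled=False, seed=None):
    """Mean DeepLIFT contribution over ``n_references`` baselines drawn from the pool."""
    pool = np.atleast_2d(np.asarray(reference_pool, dtype=float))
    if pool.shape[0] == 0:
        raise ValueError("reference pool is empty")
    if not (1 <= n_references <= pool.shape[0]):
        raise ValueError("need 1 <= n_references <= pool size")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pool.shape[0], size=n_references, replace=False)
    contribs = deeplift(model, sample, pool[idx], target_class, dropout_enabled=dropout_enabled, seed=seed)
    return np.atleast_2d(contribs).mean(axis=0)


def _last_conv_block_end(net):
    """Index just past the final conv block's ReLU (feature-map tap point)."""
    last = None
    for i, layer in enumerate(net.layers):
        if isinstance(layer, nn.Conv2d):
            last = i
    if last is None:
        raise ValueError("model has no convolutional layers")
    j = last
    while j + 1 < len(net.layers) and isinstance(net.layers[j + 1], (nn.MaxPool2d, nn.BatchNorm, nn.ReLU)):
        j += 1
    return j + 1


def guided_gradcam(model, sample, target_class, variant="gradcam", dropout_enabled=False, seed=None):
    """Guided Grad-CAM / Grad-CAM++ for CNN classifiers.

    The class-activation map over the last convolutional feature maps is
    ReLU-rectified, bilinearly upsampled to the input grid, and multiplied
    elementwise by the guided-backprop attribution of each gene's grid cell;
    pad cells are dropped by the grid-to-gene mapping.
    """
    if model.config.arch != "CNN":
        raise ValueError("GuidedGradCam(++) requires a CNN model")
    if variant not in ("gradcam", "gradcam++"):
        raise ValueError(f"unknown variant {variant!r}")
    t = _target_index(model, target_class)
    rng = _dropout_rng(dropout_enabled, seed)

    tap = _last_conv_block_end(model.net)
    masks = []
    z, caches = model.logits(sample, dropout_rng=rng, record_masks=masks)
    g_out = np.zeros_like(z)
    g_out[:, t] = 1.0
    gA = model.net.backward(g_out, caches, stop_at=tap)  # grad w.r.t. feature maps
    # recover the feature maps: output of layer tap-1
    x = np.atleast_2d(np.asarray(sample, dtype=float))
    ctx = nn.Context(replay_masks=list(masks))
    A = x
    for layer in model.net.layers[:tap]:
        A, _ = layer.forward(A, ctx)
    A, gA = A[0], gA[0]  # (C, h, w)

    if variant == "gradcam":
        w = gA.mean(axis=(1, 2))
    else:
        g2, g3 = gA**2, gA**3
        denom = 2.0 * g2 + (A * g3).sum(axis=(1, 2), keepdims=True)
        alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(np.abs(denom) > 1e-12, denom, 1.0), 0.0)
        w = (alpha * np.maximum(gA, 0.0)).sum(axis=(1, 2))
    cam = np.maximum(np.tensordot(w, A, axes=1), 0.0)  # (h, w)

    side = model.config.grid_side
    if cam.shape != (side, side):
        cam = ndimage.zoom(cam, (side / cam.shape[0], side / cam.shape[1]), order=1, grid_mode=True, mode="nearest")
        cam = cam[:side, :side]
    # guided pass reuses the same dropout mask, i.e. the same thinned network
    gg, _ = _grad(model, np.atleast_2d(sample), t, guided=True, replay_masks=list(masks))
    guided = gg[0]
    cell = model.net.layers[0].cell_of_gene()
    return guided * cam.reshape(-1)[cell]


def explain(
    explainer_id,
    model,
    sample,
    target_class,
    reference=None,
    reference_pool=None,
    n_steps=50,
    n_references=1,
    dropout_enabled=False,
    seed=None,
    sample_id="",
    model_id="",
    replicate_id=0,
    reference_descriptor="",
    signed_saliency=False,
) -> AttributionVector:
    """Uniform dispatch over the eight explainers."""
    if explainer_id not in ALL_EXPLAINERS:
        raise ValueError(f"unknown explainer {explainer_id!r}")
    if explainer_id in CNN_ONLY_EXPLAINERS and model.config.arch != "CNN":
        raise ValueError(f"{explainer_id} supports CNN models only")
    common = dict(dropout_enabled=dropout_enabled, seed=seed)
    if explainer_id == "Saliency":
        scores = saliency(model, sample, target_class, signed=signed_saliency, **common)
    elif explainer_id == "InputXGradient":
        scores = input_x_gradient(model, sample, target_class, **common)
    elif explainer_id == "GuidedBackprop":
        scores = guided_backprop(model, sample, target_class, **common)
    elif explainer_id == "IntegratedGradients":
        if reference is None:
            raise ValueError("IntegratedGradients requires a reference")
        scores = integrated_gradients(model, sample, reference, target_class, n_steps=n_steps, **common)
    elif explainer_id == "DeepLift":
        if reference is None:
            raise ValueError("DeepLift requires a reference")
        scores = deeplift(model, sample, reference, target_class, **common)
    elif explainer_id == "DeepLiftShap":
        if reference_pool is None:
            raise ValueError("DeepLiftShap requires a reference pool")
        scores = deeplift_shap(model, sample, reference_pool, target_class, n_references=n_references, **common)
    else:
        variant = "gradcam" if explainer_id == "GuidedGradCam" else "gradcam++"
        scores = guided_gradcam(model, sample, target_class, variant=variant, **common)
    return AttributionVector(
        scores=scores,
        explainer_id=explainer_id,
        sample_id=sample_id,
        model_id=model_id,
        replicate_id=replicate_id,
        target_class=target_class,
        reference_descriptor=reference_descriptor,
    )
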