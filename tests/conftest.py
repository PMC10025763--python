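import numpy as np
import pytest

import genexplain as gx
from genexplain import nn
from genexplain.models import ModelConfig, TrainedClassifier, train


@pytest.fixture(scope="session")
def toy_cohort():
    """Small separable cohort: 3 tissues, 300 genes, 30 samples/tissue."""
    design = gx.SyntheticDesign(
        n_tissues=3,
        n_genes=300,
        n_samples_per_tissue=30,
        n_markers_per_tissue=15,
        n_hk_genes=20,
        noise_sd=0.2,
        cancer_fraction=0.0,
        seed=11,
    )
    matrix, truth = gx.generate_cohort(design)
    return matrix, truth, design


@pytest.fixture(scope="session")
def toy_split(toy_cohort):
    matrix, truth, _ = toy_cohort
    return gx.split_train_test(matrix, 0.9, seed=12)


@pytest.fixture(scope="session")
def trained_mlp(toy_split):
    tr, _ = toy_split
    cfg = ModelConfig(arch="MLP", n_genes=tr.n_genes, n_classes=3, max_epochs=40, seed=13)
    return train(tr, cfg)


@pytest.fixture(scope="session")
def tiny_cnn(toy_split):
    """CNN trained on the first 64 genes (8x8 grid, small channels)."""
    tr, _ = toy_split
    sub = gx.ExpressionMatrix(
        values=tr.values[:, :64],
        gene_ids=list(tr.gene_ids[:64]),
        sample_ids=list(tr.sample_ids),
        tissue_labels=list(tr.tissue_labels),
    )
    cfg = ModelConfig(
        arch="CNN",
        n_genes=64,
        n_classes=3,
        channels=(3, 4, 4),
        kernel_sizes=(3, 3, 3),
        max_epochs=25,
        seed=14,
        gene_order=np.random.default_rng(14).permutation(64),
    )
    return train(sub, cfg)


def make_linear_model(W, b=None, class_list=None):
    """A classifier whose score is exactly x @ W + b (no hidden layers)."""
    d_in, d_out = W.shape
    cfg = ModelConfig(arch="MLP", n_genes=d_in, n_classes=d_out, dropout_p=0.0, seed=0)
    dense = nn.Dense(d_in, d_out, np.random.default_rng(0))
    dense.params["W"] = np.asarray(W, dtype=float)
    dense.params["b"] = np.zeros(d_out) if b is None else np.asarray(b, dtype=float)
    return TrainedClassifier(
        config=cfg,
        net=nn.Sequential([dense]),
        class_list=class_list or [f"c{i}" for i in range(d_out)],
    )


def make_random_relu_mlp(n_in, hidden, n_out, seed, bias_sd=0.0):
    """Random small ReLU MLP via the package's builder; optional random biases/BN stats."""
    from genexplain.models import build_model

    cfg = ModelConfig(arch="MLP", n_genes=n_in, n_classes=n_out, hidden_units=hidden, dropout_p=0.0, seed=seed)
    model = build_model(cfg)
    model.class_list = [f"c{i}" for i in range(n_out)]
    if bias_sd > 0:
        rng = np.random.default_rng(seed + 999)
        for layer in model.net.layers:
            if "b" in layer.params:
                layer.params["b"] = rng.normal(0, bias_sd, layer.params["b"].shape)
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = rng.normal(0, 0.3, layer.running_mean.shape)
                layer.running_var = rng.uniform(0.5, 2.0, layer.running_var.shape)
    return model


def finite_difference_gradient(model, x, target_idx, h=1e-4):
    """Central-difference gradient of the pre-softmax target score (test oracle)."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = h
        zp, _ = model.logits(x + e)
        zm, _ = model.logits(x - e)
        g[i] = (zp[0, target_idx] - zm[0, target_idx]) / (2 * h)
    return g
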