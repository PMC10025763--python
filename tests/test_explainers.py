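import numpy as np
import pytest

from genexplain import nn
from genexplain.models import ModelConfig, TrainedClassifier
from genexplain import explainers as ex

from conftest import finite_difference_gradient, make_linear_model, make_random_relu_mlp


@pytest.fixture
def linear_model():
    W = np.array([[1.0, -2.0], [0.5, 3.0], [-1.5, 0.25]])
    return make_linear_model(W), W


class TestSaliency:
    def test_linear_model_gives_abs_weights(self, linear_model):
        model, W = linear_model
        x = np.array([1.0, 2.0, 3.0])
        assert np.allclose(ex.saliency(model, x, 0), np.abs(W[:, 0]))
        assert np.allclose(ex.saliency(model, x, 0, signed=True), W[:, 0])

    def test_constant_model_gives_zeros(self):
        model = make_linear_model(np.zeros((4, 2)))
        assert np.allclose(ex.saliency(model, np.ones(4), 1), 0.0)

    def test_matches_finite_difference_magnitude(self):
        model = make_random_relu_mlp(6, 10, 2, seed=3, bias_sd=0.4)
        x = np.random.default_rng(3).normal(0, 1, 6)
        fd = finite_difference_gradient(model, x, 0)
        got = ex.saliency(model, x, 0)
        assert np.max(np.abs(got - np.abs(fd)) / np.maximum(np.abs(fd), 1e-6)) <= 1e-4


class TestInputXGradient:
    def test_linear_model(self, linear_model):
        model, W = linear_model
        x = np.array([2.0, -1.0, 0.5])
        assert np.allclose(ex.input_x_gradient(model, x, 1), W[:, 1] * x)

    def test_zero_input_gives_zero_scores(self, linear_model):
        model, _ = linear_model
        assert np.allclose(ex.input_x_gradient(model, np.zeros(3), 0), 0.0)

    def test_equals_signed_saliency_times_input(self):
        model = make_random_relu_mlp(7, 9, 3, seed=5, bias_sd=0.3)
        x = np.random.default_rng(5).normal(0, 1, 7)
        expected = ex.saliency(model, x, 2, signed=True) * x
        assert np.allclose(ex.input_x_gradient(model, x, 2), expected)


class TestGuidedBackprop:
    def test_linear_model_equals_plain_gradient(self, linear_model):
        model, W = linear_model
        assert np.allclose(ex.guided_backprop(model, np.ones(3), 0), W[:, 0])

    def test_all_positive_network_equals_plain_gradient(self):
        rng = np.random.default_rng(8)
        d1 = nn.Dense(4, 6, rng)
        d1.params["W"] = np.abs(d1.params["W"])
        d2 = nn.Dense(6, 2, rng)
        d2.params["W"] = np.abs(d2.params["W"])
        cfg = ModelConfig(arch="MLP", n_genes=4, n_classes=2, dropout_p=0.0)
        model = TrainedClassifier(cfg, nn.Sequential([d1, nn.ReLU(), d2]), ["a", "b"])
        x = np.abs(rng.normal(1, 0.2, 4))
        g = ex.saliency(model, x, 0, signed=True)
        assert np.allclose(ex.guided_backprop(model, x, 0), g)

    def test_negative_upstream_gradient_masked(self):
        # x -> ReLU -> (-1) * .: plain gradient is -1 for x>0, guided is 0
        d1 = nn.Dense(1, 1, np.random.default_rng(0))
        d1.params["W"] = np.array([[1.0]])
        d2 = nn.Dense(1, 1, np.random.default_rng(0))
        d2.params["W"] = np.array([[-1.0]])
        cfg = ModelConfig(arch="MLP", n_genes=1, n_classes=1, dropout_p=0.0)
        model = TrainedClassifier(cfg, nn.Sequential([d1, nn.ReLU(), d2]), ["a"])
        assert ex.guided_backprop(model, np.array([2.0]), 0)[0] == 0.0
        assert ex.saliency(model, np.array([2.0]), 0, signed=True)[0] == -1.0

    def test_masking_keeps_positive_part_of_relu_signal(self):
        # with an identity first layer, the input attribution IS the masked
        # ReLU signal: guided_i is either 0 or equals the plain gradient,
        # and is never negative where the plain gradient is negative
        n = 6
        d1 = nn.Dense(n, n, np.random.default_rng(0))
        d1.params["W"] = np.eye(n)
        d2 = nn.Dense(n, 2, np.random.default_rng(42))
        cfg = ModelConfig(arch="MLP", n_genes=n, n_classes=2, dropout_p=0.0)
        model = TrainedClassifier(cfg, nn.Sequential([d1, nn.ReLU(), d2]), ["a", "b"])
        x = np.random.default_rng(9).normal(0.5, 1.0, n)
        g = ex.saliency(model, x, 1, signed=True)
        gb = ex.guided_backprop(model, x, 1)
        for gi, gbi in zip(g, gb):
            assert gbi == pytest.approx(max(gi, 0.0) if gi != 0 else 0.0) or gbi == 0.0


class TestIntegratedGradients:
    def test_linear_model_exact_any_steps(self, linear_model):
        model, W = linear_model
        x = np.array([1.0, -2.0, 0.5])
        for n in (1, 3, 50):
            assert np.allclose(ex.integrated_gradients(model, x, np.zeros(3), 0, n_steps=n), W[:, 0] * x)

    def test_three_step_matches_independent_midpoint_sum(self):
        model = make_random_relu_mlp(5, 8, 2, seed=11, bias_sd=0.4)
        rng = np.random.default_rng(11)
        x, x0 = rng.normal(0, 1, 5), rng.normal(0, 0.2, 5)
        grads = [finite_difference_gradient(model, x0 + (k - 0.5) / 3 * (x - x0), 0) for k in (1, 2, 3)]
        expected = (x - x0) * np.mean(grads, axis=0)
        got = ex.integrated_gradients(model, x, x0, 0, n_steps=3)
        assert np.allclose(got, expected, atol=1e-6)

    def test_completeness_at_512_steps_native_init(self):
        # package init (zero biases): path crosses no ReLU kinks, midpoint rule is exact
        rng = np.random.default_rng(13)
        model = make_random_relu_mlp(8, 16, 3, seed=13)
        x = rng.normal(0, 1, 8)
        z, _ = model.logits(x)
        z0, _ = model.logits(np.zeros(8))
        dF = z[0, 1] - z0[0, 1]
        s = ex.integrated_gradients(model, x, np.zeros(8), 1, n_steps=512).sum()
        assert abs(s - dF) <= 1e-4 * abs(dF)

    def test_completeness_with_relu_kinks_decays_as_one_over_n(self):
        # with nonzero biases the directional derivative jumps at ReLU
        # crossings; midpoint error is O(#kinks / n_steps)
        rng = np.random.default_rng(14)
        errs = {}
        model = make_random_relu_mlp(8, 16, 3, seed=14, bias_sd=0.5)
        x, x0 = rng.normal(0, 1, 8), rng.normal(0, 0.3, 8)
        z, _ = model.logits(x)
        z0, _ = model.logits(x0)
        dF = z[0, 0] - z0[0, 0]
        for n in (64, 2048):
            s = ex.integrated_gradients(model, x, x0, 0, n_steps=n).sum()
            errs[n] = abs(s - dF)
        assert errs[2048] <= max(errs[64], 1e-9)
        assert errs[2048] <= 0.05 * max(abs(dF), 1e-9)

    def test_invalid_inputs_rejected(self, linear_model):
        model, _ = linear_model
        with pytest.raises(ValueError):
            ex.integrated_gradients(model, np.ones(3), np.zeros(2), 0)
        with pytest.raises(ValueError):
            ex.integrated_gradients(model, np.ones(3), np.zeros(3), 0, n_steps=0)


class TestDeepLift:
    def test_linear_model_closed_form(self, linear_model):
        model, W = linear_model
        x, x0 = np.array([1.0, 2.0, -1.0]), np.array([0.5, 0.0, 1.0])
        assert np.allclose(ex.deeplift(model, x, x0, 1), W[:, 1] * (x - x0))

    def test_pencil_and_paper_rescale_oracle(self):
        # 2-input, 2-hidden, 1-output net with fixed weights, reference 0:
        # hand-propagated Rescale multipliers give contributions [2, 8]
        d1 = nn.Dense(2, 2, np.random.default_rng(0))
        d1.params["W"] = np.array([[1.0, -1.0], [2.0, 0.5]])
        d1.params["b"] = np.array([0.5, -0.25])
        d2 = nn.Dense(2, 1, np.random.default_rng(0))
        d2.params["W"] = np.array([[2.0], [3.0]])
        d2.params["b"] = np.array([0.1])
        cfg = ModelConfig(arch="MLP", n_genes=2, n_classes=1, dropout_p=0.0)
        model = TrainedClassifier(cfg, nn.Sequential([d1, nn.ReLU(), d2]), ["a"])
        scores = ex.deeplift(model, np.array([1.0, 2.0]), np.zeros(2), 0)
        assert np.allclose(scores, [2.0, 8.0])

    def test_summation_to_delta_on_random_nets(self):
        rng = np.random.default_rng(17)
        for trial in range(30):
            model = make_random_relu_mlp(6, 10, 2, seed=trial, bias_sd=0.5)
            x, x0 = rng.normal(0, 1, 6), rng.normal(0, 0.3, 6)
            z, _ = model.logits(x)
            z0, _ = model.logits(x0)
            dF = z[0, 1] - z0[0, 1]
            s = ex.deeplift(model, x, x0, 1).sum()
            assert abs(s - dF) <= 1e-5 * max(abs(dF), 1e-6)


class TestDeepLiftShap:
    def test_singleton_pool_equals_deeplift(self, linear_model):
        model, _ = linear_model
        x = np.array([1.0, 2.0, 3.0])
        ref = np.array([[0.1, 0.2, 0.3]])
        assert np.allclose(
            ex.deeplift_shap(model, x, ref, 0, n_references=1, seed=0),
            ex.deeplift(model, x, ref[0], 0),
        )

    def test_linear_model_mean_reference(self, linear_model):
        model, W = linear_model
        x = np.array([1.0, -1.0, 2.0])
        pool = np.random.default_rng(19).random((10, 3))
        got = ex.deeplift_shap(model, x, pool, 0, n_references=10, seed=1)
        assert np.allclose(got, W[:, 0] * (x - pool.mean(axis=0)))

    def test_averaged_summation_to_delta(self):
        model = make_random_relu_mlp(5, 8, 2, seed=23, bias_sd=0.4)
        rng = np.random.default_rng(23)
        x = rng.normal(0, 1, 5)
        pool = rng.normal(0, 0.3, (6, 5))
        got = ex.deeplift_shap(model, x, pool, 0, n_references=6, seed=2).sum()
        z, _ = model.logits(x)
        z0, _ = model.logits(pool)
        dF = z[0, 0] - z0[:, 0].mean()
        assert abs(got - dF) <= 1e-5 * max(abs(dF), 1e-6)

    def test_full_pool_invariant_to_order(self, linear_model):
        model, _ = linear_model
        x = np.ones(3)
        pool = np.random.default_rng(29).random((5, 3))
        a = ex.deeplift_shap(model, x, pool, 0, n_references=5, seed=0)
        b = ex.deeplift_shap(model, x, pool[::-1], 0, n_references=5, seed=7)
        assert np.allclose(a, b)

    def test_empty_pool_rejected(self, linear_model):
        model, _ = linear_model
        with pytest.raises(ValueError):
            ex.deeplift_shap(model, np.ones(3), np.empty((0, 3)), 0)


def _toy_cam_cnn(conv_w=2.0, dense_w=4.0, n_genes=4, side=2):
    reshape = nn.GridReshape(np.arange(n_genes), side)
    conv = nn.Conv2d(1, 1, 1, np.random.default_rng(0))
    conv.params["W"] = np.array([[[[conv_w]]]])
    conv.params["b"] = np.zeros(1)
    dense = nn.Dense(1, 1, np.random.default_rng(0))
    dense.params["W"] = np.array([[dense_w]])
    cfg = ModelConfig(arch="CNN", n_genes=n_genes, n_classes=1, grid_side=side,
                      channels=(1,), kernel_sizes=(1,), dropout_p=0.0)
    return TrainedClassifier(cfg, nn.Sequential([reshape, conv, nn.GlobalAvgPool(), dense]), ["a"])


class TestGuidedGradCam:
    def test_manual_oracle_single_channel(self):
        # A = 2x per cell, dF/dA = 1 per cell, guided grad = 2 per gene
        # grad-cam: cam = A -> scores = 2 * [2,4,6,8]
        model = _toy_cam_cnn()
        x = np.array([1.0, 2.0, 3.0, 4.0])
        got = ex.guided_gradcam(model, x, 0, variant="gradcam")
        assert np.allclose(got, [4.0, 8.0, 12.0, 16.0])

    def test_manual_oracle_gradcam_pp(self):
        # alpha = 1/(2 + sum A) = 1/22 per cell, w = 4/22, cam = (2/11) A
        model = _toy_cam_cnn()
        x = np.array([1.0, 2.0, 3.0, 4.0])
        got = ex.guided_gradcam(model, x, 0, variant="gradcam++")
        assert np.allclose(got, np.array([8.0, 16.0, 24.0, 32.0]) / 11.0)

    def test_zero_feature_gradients_give_zero_scores(self):
        model = _toy_cam_cnn(dense_w=0.0)
        got = ex.guided_gradcam(model, np.ones(4), 0)
        assert np.allclose(got, 0.0)

    def test_output_length_equals_gene_count_despite_padding(self):
        model = _toy_cam_cnn(n_genes=3, side=2)
        got = ex.guided_gradcam(model, np.ones(3), 0)
        assert got.shape == (3,)

    def test_mlp_rejected(self, linear_model):
        model, _ = linear_model
        with pytest.raises(ValueError, match="CNN"):
            ex.guided_gradcam(model, np.ones(3), 0)

    def test_runs_on_trained_cnn(self, tiny_cnn):
        x = np.random.default_rng(1).random(64)
        for variant in ("gradcam", "gradcam++"):
            got = ex.guided_gradcam(tiny_cnn, x, 0, variant=variant)
            assert got.shape == (64,) and np.all(np.isfinite(got))


class TestDispatch:
    def test_dispatch_equals_direct_call(self, trained_mlp, toy_split):
        _, te = toy_split
        x, t = te.values[0], te.tissue_labels[0]
        v = ex.explain("Saliency", trained_mlp, x, t)
        assert np.array_equal(v.scores, ex.saliency(trained_mlp, x, t))

    def test_deterministic_without_dropout(self, trained_mlp, toy_split):
        _, te = toy_split
        x, t = te.values[0], te.tissue_labels[0]
        a = ex.explain("GuidedBackprop", trained_mlp, x, t)
        b = ex.explain("GuidedBackprop", trained_mlp, x, t)
        assert np.array_equal(a.scores, b.scores)

    def test_dropout_seeding_contract(self, trained_mlp, toy_split):
        _, te = toy_split
        x, t = te.values[0], te.tissue_labels[0]
        a = ex.explain("DeepLift", trained_mlp, x, t, reference=np.zeros(te.n_genes),
                       dropout_enabled=True, seed=3)
        b = ex.explain("DeepLift", trained_mlp, x, t, reference=np.zeros(te.n_genes),
                       dropout_enabled=True, seed=3)
        c = ex.explain("DeepLift", trained_mlp, x, t, reference=np.zeros(te.n_genes),
                       dropout_enabled=True, seed=4)
        assert np.array_equal(a.scores, b.scores)
        assert not np.array_equal(a.scores, c.scores)

    def test_gradcam_on_mlp_rejected(self, trained_mlp, toy_split):
        _, te = toy_split
        with pytest.raises(ValueError):
            ex.explain("GuidedGradCam", trained_mlp, te.values[0], te.tissue_labels[0])

    def test_unknown_explainer_rejected(self, trained_mlp, toy_split):
        _, te = toy_split
        with pytest.raises(ValueError):
            ex.explain("Occlusion", trained_mlp, te.values[0], te.tissue_labels[0])


class TestPermutationInvariance:
    @pytest.mark.parametrize("explainer", ["Saliency", "InputXGradient", "GuidedBackprop",
                                           "IntegratedGradients", "DeepLift"])
    def test_mlp_attributions_permute_with_inputs(self, explainer):
        rng = np.random.default_rng(31)
        model = make_random_relu_mlp(8, 12, 2, seed=31, bias_sd=0.3)
        perm = rng.permutation(8)
        permuted = make_random_relu_mlp(8, 12, 2, seed=31, bias_sd=0.3)
        W = model.net.layers[0].params["W"]
        permuted.net.layers[0].params["W"] = W[perm]
        x = rng.normal(0, 1, 8)
        kwargs = {}
        if explainer in ("IntegratedGradients", "DeepLift"):
            kwargs["reference"] = np.zeros(8)
        a = ex.explain(explainer, model, x, 0, **kwargs).scores
        b = ex.explain(explainer, permuted, x[perm], 0,
                       **({"reference": np.zeros(8)} if kwargs else {})).scores
        assert np.allclose(b, a[perm], atol=1e-10)
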