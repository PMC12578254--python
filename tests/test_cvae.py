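"""Conditional VAE: shapes, closed forms, gradients, training dynamics and
label-controlled generation."""

import numpy as np
import pytest

from eegcvae.cvae import (CVAEConfig, LatentStats, _forward_backward,
                          classify, classify_logits, count_parameters, decode,
                          encode, evaluate_accuracy, generate, init_model,
                          kl_divergence, load_model, median_heuristic,
                          mmd_unbiased, objective, predict, reparameterize,
                          save_model, train, weighted_cross_entropy)
from eegcvae.preprocess import ClassWeights

SMALL = CVAEConfig(d_feat=10, d_z=4, encoder_widths=(8, 6),
                   decoder_widths=(6, 8), seed=3)


def affine(i, o):
    return i * o + o


class TestArchitecture:
    def test_default_parameter_count_matches_printed_total(self):
        model = init_model(CVAEConfig())
        assert count_parameters(model) == 18938

    def test_classifier_head_size(self):
        model = init_model(CVAEConfig())
        assert model.params["clf.W"].size + model.params["clf.b"].size == 66

    def test_reduced_latent_matches_affine_arithmetic(self):
        cfg = CVAEConfig(d_z=8)
        expected = (affine(89, 64) + affine(64, 32) + 2 * affine(32, 8)
                    + affine(9, 32) + affine(32, 64) + affine(64, 88)
                    + affine(8, 2))
        assert count_parameters(init_model(cfg)) == expected

    def test_encoder_consumes_89_decoder_33(self):
        model = init_model(CVAEConfig())
        assert model.params["enc1.W"].shape == (89, 64)
        assert model.params["dec1.W"].shape == (33, 32)

    def test_shapes_through_the_network(self, rng):
        model = init_model(CVAEConfig())
        x = rng.standard_normal((5, 88))
        y = np.array([0, 1, 0, 1, 1])
        ls = encode(model, x, y)
        assert ls.mu.shape == ls.log_var.shape == (5, 32)
        z = reparameterize(ls, np.zeros((5, 32)))
        assert decode(model, z, y).shape == (5, 88)
        assert classify_logits(model, z).shape == (5, 2)


class TestEncodeDecode:
    def test_label_reaches_encoder(self, rng):
        model = init_model(CVAEConfig())
        x = rng.standard_normal((1, 88))
        mu0 = encode(model, x, np.array([0])).mu
        mu1 = encode(model, x, np.array([1])).mu
        assert not np.allclose(mu0, mu1)

    def test_zero_input_zero_bias_gives_zero_mu(self):
        model = init_model(CVAEConfig())
        for name, p in model.params.items():
            if name.endswith(".b"):
                p[:] = 0.0
        ls = encode(model, np.zeros((1, 88)), np.array([0]))
        assert np.allclose(ls.mu, 0.0)

    def test_nonbinary_label_rejected(self, rng):
        model = init_model(CVAEConfig())
        with pytest.raises(ValueError):
            encode(model, rng.standard_normal((1, 88)), np.array([2]))

    def test_label_reaches_decoder(self, rng):
        model = init_model(CVAEConfig())
        z = rng.standard_normal((1, 32))
        assert not np.allclose(decode(model, z, np.array([0])),
                               decode(model, z, np.array([1])))

    def test_zero_weights_decode_to_bias(self):
        model = init_model(CVAEConfig())
        for name, p in model.params.items():
            if name.startswith("dec") and name.endswith(".W"):
                p[:] = 0.0
        out = decode(model, np.ones((1, 32)), np.array([1]))
        # relu(relu(b1) W2 + b2) W3 + b3 with W=0 collapses to b3
        assert np.allclose(out, model.params["dec3.b"])

    def test_reparameterize_identities(self, rng):
        mu = rng.standard_normal((3, 32))
        ls = LatentStats(mu=mu, log_var=np.zeros((3, 32)))
        assert np.array_equal(reparameterize(ls, np.zeros((3, 32))), mu)
        eps = rng.standard_normal((3, 32))
        ls0 = LatentStats(mu=np.zeros((3, 32)), log_var=np.zeros((3, 32)))
        assert np.array_equal(reparameterize(ls0, eps), eps)


class TestDivergences:
    def test_kl_standard_normal_is_zero(self):
        assert kl_divergence(LatentStats(np.zeros((1, 32)), np.zeros((1, 32)))) == 0.0

    def test_kl_unit_mean_shift(self):
        assert kl_divergence(LatentStats(np.ones((1, 32)),
                                         np.zeros((1, 32)))) == pytest.approx(16.0)

    def test_kl_single_dim_variance_two(self):
        ls = LatentStats(np.zeros((1, 1)), np.log(2.0) * np.ones((1, 1)))
        assert kl_divergence(ls) == pytest.approx(0.15343, abs=1e-5)

    def test_kl_nonnegative_zero_only_at_prior(self, rng):
        for _ in range(100):
            ls = LatentStats(rng.standard_normal((1, 8)),
                             rng.standard_normal((1, 8)))
            kl = kl_divergence(ls)
            assert kl > 0.0
        assert kl_divergence(LatentStats(np.zeros((1, 8)), np.zeros((1, 8)))) == 0.0

    def test_mmd_hand_enumerated_case(self):
        z = np.array([[0.0], [1.0]])
        assert mmd_unbiased(z, z.copy(), bandwidth=1.0) == pytest.approx(
            np.exp(-0.5) - 1.0, abs=1e-12)

    def test_mmd_identical_points_zero(self):
        z = np.array([[3.0], [3.0]])
        assert mmd_unbiased(z, z.copy(), bandwidth=1.0) == 0.0

    def test_mmd_concentrates_at_zero_under_the_prior(self):
        vals = [mmd_unbiased(np.random.default_rng(s).standard_normal((500, 32)),
                             np.random.default_rng(1000 + s).standard_normal((500, 32)))
                for s in range(20)]
        assert np.max(np.abs(vals)) < 0.01

    def test_mmd_symmetry_and_wide_kernel_limit(self, rng):
        a, b = rng.standard_normal((6, 4)), rng.standard_normal((9, 4)) + 1.0
        assert mmd_unbiased(a, b) == pytest.approx(mmd_unbiased(b, a), abs=1e-12)
        assert abs(mmd_unbiased(a, b, bandwidth=1e12)) < 1e-9

    def test_mmd_needs_two_samples(self, rng):
        with pytest.raises(ValueError):
            mmd_unbiased(rng.standard_normal((1, 4)), rng.standard_normal((5, 4)))

    def test_median_heuristic_positive(self, rng):
        assert median_heuristic(rng.standard_normal((8, 4)),
                                rng.standard_normal((8, 4))) > 0


class TestClassifierAndObjective:
    def test_zero_parameters_give_uniform_probabilities(self):
        model = init_model(CVAEConfig())
        model.params["clf.W"][:] = 0.0
        model.params["clf.b"][:] = 0.0
        probs = classify(model, np.ones((3, 32)))
        assert np.allclose(probs, 0.5)

    def test_softmax_closed_form(self):
        p = 1.0 / (1.0 + np.exp(-20.0))
        logits = np.array([[10.0, -10.0]])
        loss, _ = weighted_cross_entropy(logits, np.array([0]))
        assert loss == pytest.approx(-np.log(p), rel=1e-9)

    def test_unit_weights_equal_unweighted(self, rng):
        logits = rng.standard_normal((16, 2))
        y = rng.integers(0, 2, 16)
        plain, _ = weighted_cross_entropy(logits, y)
        weighted, _ = weighted_cross_entropy(logits, y, ClassWeights(1.0, 1.0))
        assert plain == pytest.approx(weighted, rel=1e-12)

    def test_divergence_multiplier_at_defaults(self):
        cfg = CVAEConfig()
        assert cfg.lambda_div * cfg.beta == pytest.approx(1e-3)

    def test_recon_term_is_mse_per_feature(self, rng):
        model = init_model(CVAEConfig(d_feat=10, d_z=4, encoder_widths=(8, 6),
                                      decoder_widths=(6, 8)))
        for p in model.params.values():
            p[:] = 0.0
        x = np.ones((4, 10))
        val = objective(model, x, np.array([0, 1, 0, 1]),
                        eps=np.zeros((4, 4)))
        # zero network reconstructs 0, so MSE per feature of ones is exactly 1
        assert val.recon == pytest.approx(1.0)
        assert val.div == 0.0


class TestGradients:
    def test_kl_gradient_closed_form_mu(self, rng):
        """d KL / d mu_i = mu_i, checked by finite differences."""
        mu = rng.standard_normal(8)
        h = 1e-6
        for i in range(8):
            up, dn = mu.copy(), mu.copy()
            up[i] += h
            dn[i] -= h
            num = (kl_divergence(LatentStats(up[None], np.zeros((1, 8))))
                   - kl_divergence(LatentStats(dn[None], np.zeros((1, 8))))) / (2 * h)
            assert num == pytest.approx(mu[i], abs=1e-4)

    @pytest.mark.parametrize("divergence", ["kl", "mmd"])
    def test_backward_matches_finite_differences(self, rng, divergence):
        cfg = CVAEConfig(d_feat=10, d_z=4, encoder_widths=(8, 6),
                         decoder_widths=(6, 8), divergence=divergence, seed=3)
        model = init_model(cfg)
        x = rng.standard_normal((6, 10))
        y = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        eps = rng.standard_normal((6, 4))
        w = ClassWeights(1.2, 0.8)
        zp = rng.standard_normal((6, 4)) if divergence == "mmd" else None
        _, grads = _forward_backward(model, x, y, eps, w, zp)
        h = 1e-6
        check = rng
        for name in ("enc1.W", "mu.W", "log_var.b", "dec2.W", "clf.W"):
            arr = model.params[name]
            flat = arr.reshape(-1)
            n_probe = min(5, flat.size)
            for idx in check.choice(flat.size, size=n_probe, replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                vp, _ = _forward_backward(model, x, y, eps, w, zp)
                flat[idx] = orig - h
                vm, _ = _forward_backward(model, x, y, eps, w, zp)
                flat[idx] = orig
                num = (vp.total - vm.total) / (2 * h)
                assert num == pytest.approx(grads[name].reshape(-1)[idx],
                                            abs=2e-5)


class TestTraining:
    def test_separated_classes_reach_high_heldout_accuracy(
            self, trained_separated_model):
        _, traces, _ = trained_separated_model
        assert traces["val_acc"].iloc[-1] >= 0.95

    def test_indistinguishable_classes_stay_at_chance(self):
        gen = np.random.default_rng(99)
        x = gen.standard_normal((2000, 88))
        y = np.repeat([0, 1], 1000)[gen.permutation(2000)]
        _, traces = train(x[:1600], y[:1600], CVAEConfig(seed=7),
                          x_val=x[1600:], y_val=y[1600:])
        assert abs(traces["val_acc"].iloc[-1] - 0.5) <= 0.05

    def test_total_loss_decreases_early(self, trained_separated_model):
        _, traces, _ = trained_separated_model
        assert traces["total"].iloc[4] < traces["total"].iloc[0]

    def test_identical_seeds_identical_losses(self, separated_features):
        x, y, _ = separated_features
        cfg = CVAEConfig(seed=13, epochs=5)
        _, t1 = train(x[:640], y[:640], cfg)
        _, t2 = train(x[:640], y[:640], cfg)
        assert t1["total"].tolist() == t2["total"].tolist()

    def test_mmd_divergence_trains(self, separated_features):
        x, y, _ = separated_features
        cfg = CVAEConfig(seed=7, epochs=10, divergence="mmd")
        _, traces = train(x[:640], y[:640], cfg, x_val=x[1600:], y_val=y[1600:])
        assert traces["val_acc"].iloc[-1] >= 0.9

    def test_traces_record_batch_dispersion(self, trained_separated_model):
        _, traces, _ = trained_separated_model
        assert {"clf_std_batch", "total_std_batch"} <= set(traces.columns)


class TestGeneration:
    def test_output_shape_and_determinism(self, trained_separated_model):
        model, _, _ = trained_separated_model
        a = generate(model, 1, 10, seed=7)
        b = generate(model, 1, 10, seed=7)
        assert a.shape == (10, 88)
        assert np.array_equal(a, b)

    def test_injected_shift_signs_recovered(self, trained_separated_model):
        """Generated class means reproduce the sign of every injected
        per-feature shift (the binomial criterion is >= 80% of 88 dims)."""
        model, _, shift = trained_separated_model
        g0 = generate(model, 0, 500, seed=11).mean(axis=0)
        g1 = generate(model, 1, 500, seed=12).mean(axis=0)
        assert (((g1 - g0) * shift) > 0).mean() >= 0.80

    def test_invalid_label_rejected(self, trained_separated_model):
        model, _, _ = trained_separated_model
        with pytest.raises(ValueError):
            generate(model, 2, 5, seed=0)


class TestPersistence:
    def test_checkpoint_roundtrip_preserves_predictions(
            self, trained_separated_model, separated_features, tmp_path):
        model, _, _ = trained_separated_model
        x, y, _ = separated_features
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        assert back.config == model.config
        assert np.array_equal(predict(back, x[:100]), predict(model, x[:100]))
        assert evaluate_accuracy(back, x[1600:], y[1600:]) == \
            evaluate_accuracy(model, x[1600:], y[1600:])
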