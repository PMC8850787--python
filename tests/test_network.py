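"""Architecture contracts: shapes, gradient reversal, λ schedule, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from badacount import autodiff as ad
from badacount.autodiff import Tensor
from badacount.losses import adversarial_loss, make_domain_labels
from badacount.network import BadaModel, ModelConfig, grad_reverse, lambda_schedule


@pytest.fixture(scope="module")
def tiny_model():
    return BadaModel(ModelConfig.tiny(seed=3))


@pytest.fixture(scope="module")
def full_model():
    return BadaModel(ModelConfig.full(seed=3))


def _image(rng, h, w):
    return rng.random((h, w, 3))


class TestShapeContracts:
    def test_full_profile_composition_at_512(self, full_model, rng):
        with ad.no_grad():  # inference: the full graph would not fit in RAM
            out = full_model.forward_full(_image(rng, 512, 512), lam=0.3)
        assert out.m_f.shape == (1, 512, 64, 64)
        assert out.m_c.shape == (1, 64, 64, 64)
        assert out.seg_probs.shape == (1, 2, 64, 64)
        assert out.m_s.shape == (1, 1, 64, 64)
        assert out.c_est.shape == (1, 1, 8, 8)
        assert out.disc_f.shape == (1, 2, 16, 16)
        assert out.disc_m.shape == (1, 2, 16, 16)

    def test_tiny_profile_shapes(self, tiny_model, rng):
        out = tiny_model.forward_full(_image(rng, 128, 128), lam=0.0)
        assert out.m_f.shape == (1, 32, 16, 16)
        assert out.c_est.shape == (1, 1, 2, 2)
        assert out.disc_f.shape == (1, 2, 4, 4)
        out64 = tiny_model.forward_full(_image(rng, 64, 64))
        assert out64.c_est.shape == (1, 1, 1, 1)

    def test_profiles_share_one_code_path(self, tiny_model, full_model):
        assert type(tiny_model) is type(full_model)
        # components differ only through the config: same layer structure
        assert len(full_model.regressor) == len(tiny_model.regressor) == 3
        assert len(full_model.disc_f_layers) == len(tiny_model.disc_f_layers) == 3

    def test_density_ablation_head_resolution(self, rng):
        model = BadaModel(ModelConfig.tiny(seed=0, head="density"))
        out = model.forward_full(_image(rng, 128, 128))
        assert out.density.shape == (1, 1, 16, 16)
        assert out.c_est is None

    def test_indivisible_input_rejected_with_padding_hint(self, tiny_model, rng):
        with pytest.raises(ValueError, match="divisible by 8"):
            tiny_model.encode(_image(rng, 60, 64))
        with pytest.raises(ValueError, match="divisible by 64"):
            tiny_model.forward_full(_image(rng, 72, 72))

    def test_segmentation_probabilities_normalised(self, tiny_model, rng):
        out = tiny_model.forward_full(_image(rng, 64, 64))
        np.testing.assert_allclose(out.seg_probs.data.sum(axis=1), 1.0, atol=1e-6)
        assert (out.m_s.data >= 0).all() and (out.m_s.data <= 1).all()

    def test_counts_nonnegative(self, tiny_model, rng):
        for _ in range(3):
            out = tiny_model.forward_full(_image(rng, 64, 64))
            assert (out.c_est.data >= 0).all()

    def test_discriminator_small_input_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="smaller than 4x4"):
            tiny_model.discriminate_features(Tensor(np.zeros((1, 32, 2, 2))))

    def test_zero_features_with_zero_biases_decode_to_zero(self, tiny_model):
        z = Tensor(np.zeros((1, 32, 8, 8)))
        assert not tiny_model.decode_counting(z).data.any()


class TestDeterminism:
    def test_same_seed_same_outputs(self, rng):
        img = _image(rng, 64, 64)
        a = BadaModel(ModelConfig.tiny(seed=11)).predict(img)
        b = BadaModel(ModelConfig.tiny(seed=11)).predict(img)
        np.testing.assert_array_equal(a, b)

    def test_different_seed_different_weights(self):
        a = BadaModel(ModelConfig.tiny(seed=1)).encoder_parameters()[0].data
        b = BadaModel(ModelConfig.tiny(seed=2)).encoder_parameters()[0].data
        assert not np.array_equal(a, b)

    def test_disabling_discriminators_keeps_shared_initial_weights(self):
        full = BadaModel(ModelConfig.tiny(seed=5, use_discriminators=True))
        bare = BadaModel(ModelConfig.tiny(seed=5, use_discriminators=False))
        for pa, pb in zip(full.main_parameters(), bare.main_parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestGradReverse:
    def test_forward_is_identity(self, rng):
        x = rng.normal(size=(3, 4))
        np.testing.assert_array_equal(grad_reverse(Tensor(x), 0.7).data, x)

    def test_lambda_zero_blocks_gradient(self, rng):
        x = Tensor(rng.normal(size=(3, 3)), requires_grad=True)
        (grad_reverse(x, 0.0) ** 2).sum().backward()
        np.testing.assert_array_equal(x.grad, np.zeros((3, 3)))

    @pytest.mark.parametrize("lam", [0.0, 0.3, 0.7, 1.0])
    def test_backward_is_minus_lambda_times_upstream(self, lam):
        # f(R(x)) = x**2 must report d/dx = -lam * 2x
        x0 = np.array([1.5, -0.4, 2.0])
        x = Tensor(x0, requires_grad=True)
        (grad_reverse(x, lam) ** 2).sum().backward()
        eps = 1e-6
        fd = np.array(
            [
                (float((Tensor(x0 + eps * e) ** 2).sum()) - float((Tensor(x0 - eps * e) ** 2).sum()))
                / (2 * eps)
                for e in np.eye(3)
            ]
        )
        np.testing.assert_allclose(x.grad, -lam * fd, rtol=1e-5, atol=1e-9)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            grad_reverse(Tensor(np.zeros(2)), -0.1)

    def test_lambda_zero_freezes_encoder_against_adversarial_loss(self, rng):
        model = BadaModel(ModelConfig.tiny(seed=2))
        out = model.forward_full(_image(rng, 64, 64), lam=0.0)
        loss = adversarial_loss(
            model.source_probability(out.disc_f),
            model.source_probability(out.disc_m),
            make_domain_labels("source", out.disc_f.shape[-2:])[None, None],
        )
        loss.backward()
        for p in model.encoder_parameters():
            assert p.grad is None or not p.grad.any()
        assert any(
            p.grad is not None and p.grad.any() for p in model.discriminator_parameters()
        )


class TestLambdaSchedule:
    def test_starts_at_zero(self):
        assert lambda_schedule(0.0, 5.0) == 0.0

    def test_endpoint_closed_form(self):
        assert lambda_schedule(1.0, 10.0) == pytest.approx(
            2.0 / (1.0 + np.exp(-10.0)) - 1.0, abs=1e-12
        )
        assert lambda_schedule(1.0, 10.0) == pytest.approx(0.99991, abs=1e-5)

    def test_monotone_on_dense_grid(self):
        grid = [lambda_schedule(p, 10.0) for p in np.linspace(0, 1, 1000)]
        assert all(b >= a for a, b in zip(grid, grid[1:]))
        assert grid[-1] < 1.0

    @settings(deadline=None, max_examples=100)
    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0.1, 50)
    )
    def test_monotone_property(self, p1, p2, gamma):
        lo, hi = sorted((p1, p2))
        assert lambda_schedule(hi, gamma) >= lambda_schedule(lo, gamma)

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert lambda_schedule(1.5, 10.0) == lambda_schedule(1.0, 10.0)


class TestConfigValidation:
    def test_unknown_profile_and_head_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(profile="huge")
        with pytest.raises(ValueError):
            ModelConfig(head="classification")
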