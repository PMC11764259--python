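"""Loss terms: exact-match zeros, worked arithmetic, weight linearity and
gradient correctness on small instances."""

import numpy as np
import pytest

from cyclereg._autodiff import Tensor
from cyclereg.io_formats import RegistrationConfig
from cyclereg.losses import (cycle_loss, functional_loss, identity_loss,
                             lfc_loss, similarity_mse, similarity_mse_t,
                             smoothness, smoothness_t, structural_loss,
                             total_loss)
from cyclereg.registration_network import RegistrationNetwork
from cyclereg.spatial_transform import DeformationField, base_grid, warp_tensor
from cyclereg.synthetic_data import make_functional_series, make_structural_pair

from conftest import numeric_gradient

rng = np.random.default_rng(0)


class TestSimilarity:
    def test_identical_images_zero(self):
        a = rng.random((5, 5, 5))
        assert similarity_mse(a, a) == 0.0

    def test_constant_offset_of_one(self):
        a = rng.random((5, 5, 5))
        assert similarity_mse(a, a + 1.0) == pytest.approx(1.0)

    def test_symmetric(self):
        a, b = rng.random((4, 4, 4)), rng.random((4, 4, 4))
        assert similarity_mse(a, b) == pytest.approx(similarity_mse(b, a))

    def test_4d_supported(self):
        a = rng.random((4, 4, 4, 3))
        assert similarity_mse(a, a + 2.0) == pytest.approx(4.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            similarity_mse(np.zeros((4, 4, 4)), np.zeros((5, 5, 5)))


class TestSmoothness:
    def test_constant_displacement_zero(self):
        assert smoothness(np.ones((3, 5, 5, 5)) * 4.2) == 0.0

    def test_unit_gradient_ramp(self):
        u = np.zeros((3, 6, 6, 6))
        u[0] = base_grid((6, 6, 6))[0]       # u_x = x
        assert smoothness(u) == pytest.approx(1.0)

    def test_zero_field_zero(self):
        assert smoothness(DeformationField.zero((5, 5, 5))) == 0.0


class TestLfcLoss:
    def test_identical_series_zero(self):
        s = rng.standard_normal((4, 4, 4, 10))
        assert lfc_loss(s, s, n_points=8) < 1e-5

    def test_symmetric(self):
        a = rng.standard_normal((4, 4, 4, 10))
        b = rng.standard_normal((4, 4, 4, 10))
        assert lfc_loss(a, b, n_points=8) == pytest.approx(lfc_loss(b, a, n_points=8))

    def test_swapped_latents_positive(self):
        pair = make_structural_pair((16, 16, 16), n_structures=2, seed=3)
        a = make_functional_series(pair.fixed_labels, T=60, snr=5, seed=0)
        b = make_functional_series(pair.fixed_labels, T=60, snr=5, seed=99)
        assert lfc_loss(a, b, n_points=16) > 0.0


class TestStructuralLoss:
    def test_matched_pair_zero_fields(self):
        a = rng.random((6, 6, 6))
        z = DeformationField.zero((6, 6, 6))
        assert structural_loss(a, a, z, z) == pytest.approx(0.0)

    def test_lambda_zero_reduces_to_mse(self):
        a, b = rng.random((6, 6, 6)), rng.random((6, 6, 6))
        u1 = DeformationField(rng.uniform(-1, 1, (3, 6, 6, 6)))
        u2 = DeformationField(rng.uniform(-1, 1, (3, 6, 6, 6)))
        got = structural_loss(a, b, u1, u2, smooth_weight=0.0)
        mse1 = similarity_mse_t(Tensor(b), warp_tensor(Tensor(a), Tensor(u1.u))).item()
        mse2 = similarity_mse_t(Tensor(a), warp_tensor(Tensor(b), Tensor(u2.u))).item()
        assert got == pytest.approx(mse1 + mse2)

    def test_symmetric_under_joint_swap(self):
        a, b = rng.random((6, 6, 6)), rng.random((6, 6, 6))
        u1 = DeformationField(rng.uniform(-1, 1, (3, 6, 6, 6)))
        u2 = DeformationField(rng.uniform(-1, 1, (3, 6, 6, 6)))
        assert structural_loss(a, b, u1, u2) == pytest.approx(
            structural_loss(b, a, u2, u1))


class TestFunctionalLoss:
    def test_matched_zero(self):
        x = rng.standard_normal((4, 4, 4, 8))
        z = DeformationField.zero((4, 4, 4))
        assert functional_loss(x, x, z, z, n_points=8) < 1e-5

    def test_nonnegative(self):
        x = rng.standard_normal((4, 4, 4, 8))
        y = rng.standard_normal((4, 4, 4, 8))
        u1 = DeformationField(rng.uniform(-1, 1, (3, 4, 4, 4)))
        u2 = DeformationField(rng.uniform(-1, 1, (3, 4, 4, 4)))
        assert functional_loss(x, y, u1, u2, n_points=8) >= 0.0

    def test_lfc_off_reduces_to_mse_terms(self):
        x = rng.standard_normal((4, 4, 4, 8))
        y = rng.standard_normal((4, 4, 4, 8))
        z = DeformationField.zero((4, 4, 4))
        got = functional_loss(x, y, z, z, use_lfc=False)
        assert got == pytest.approx(2 * similarity_mse(x, y))


class TestCycleLoss:
    def test_identity_configuration_zero(self):
        a = rng.random((6, 6, 6))
        z = DeformationField.zero((6, 6, 6))
        assert cycle_loss(a, a, z, z, z, z) == 0.0

    def test_inverse_translation_interior_zero(self):
        # +1 voxel then -1 voxel returns every interior voxel exactly
        ramp = np.arange(8 ** 3, dtype=float).reshape(8, 8, 8)
        fwd = np.zeros((3, 8, 8, 8))
        fwd[0] = 1.0
        bwd = np.zeros((3, 8, 8, 8))
        bwd[0] = -1.0
        f_fwd, f_bwd = DeformationField(fwd), DeformationField(bwd)
        z = DeformationField.zero((8, 8, 8))
        # second-pass fields undo the first pass in each chain
        from cyclereg._autodiff import Tensor as T
        bp = warp_tensor(T(ramp), T(fwd)).data
        a2 = warp_tensor(T(bp), T(bwd)).data
        assert np.abs(a2[1:, :, :] - ramp[1:, :, :]).max() < 1e-12

    def test_nonnegative(self):
        a, b = rng.random((6, 6, 6)), rng.random((6, 6, 6))
        us = [DeformationField(rng.uniform(-1, 1, (3, 6, 6, 6))) for _ in range(4)]
        assert cycle_loss(a, b, *us) >= 0.0


class TestIdentityLoss:
    def test_zero_field_networks_zero(self, tiny_config):
        g_a = RegistrationNetwork(tiny_config, seed=0)
        g_b = RegistrationNetwork(tiny_config, seed=1)
        for net in (g_a, g_b):
            for p in (net.head_w, net.head_b, net.head_coarse_w, net.head_coarse_b):
                p.data[:] = 0.0
        a, b = rng.random((12, 12, 12)), rng.random((12, 12, 12))
        assert identity_loss(a, b, g_a, g_b) == 0.0

    def test_nonzero_field_on_ramp_positive(self, tiny_config):
        g_a = RegistrationNetwork(tiny_config, seed=0)
        g_b = RegistrationNetwork(tiny_config, seed=1)
        for net in (g_a, g_b):
            net.head_b.data[:] = 0.5       # forces a nonzero field
        ramp = base_grid((12, 12, 12))[0] / 12.0
        assert identity_loss(ramp, ramp, g_a, g_b) > 0.0


class TestTotalLoss:
    def test_weighted_arithmetic(self):
        report = total_loss(1.0, 2.0, 3.0, 4.0)
        assert report.total == pytest.approx(1 + 0.4 + 0.3 + 2.0)
        assert report.total == pytest.approx(3.7)

    def test_zero_weights_leave_structural_term(self):
        report = total_loss(1.5, 2.0, 3.0, 4.0, alpha=0, beta=0, gamma=0)
        assert report.total == 1.5

    def test_all_zero(self):
        assert total_loss(0, 0, 0, 0).total == 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            total_loss(1, 1, 1, 1, alpha=-0.1)

    @pytest.mark.parametrize("component,weight", [
        ("l_register_mri", 1.0), ("l_register_fmri", 0.2),
        ("l_cycle", 0.1), ("l_identity", 0.5),
    ])
    def test_linearity_in_each_component(self, component, weight):
        base = dict(l_register_mri=1.0, l_register_fmri=1.0,
                    l_cycle=1.0, l_identity=1.0)
        bumped = dict(base)
        bumped[component] += 1.0
        delta = total_loss(**bumped).total - total_loss(**base).total
        assert delta == pytest.approx(weight)


class TestLossGradients:
    def test_structural_objective_gradient_on_toy_instance(self):
        a = Tensor(rng.random((6, 6, 6)))
        b = Tensor(rng.random((6, 6, 6)))
        u = Tensor(rng.uniform(-0.8, 0.8, (3, 6, 6, 6)), requires_grad=True)

        def objective():
            warped = warp_tensor(a, u)
            return similarity_mse_t(b, warped) + 0.02 * smoothness_t(u)

        objective().backward()
        num = numeric_gradient(u, lambda: objective().item(), sample_every=11)
        mask = num != 0
        assert np.abs(u.grad[mask] - num[mask]).max() < 1e-3
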