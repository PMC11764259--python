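"""Training loop contracts: determinism, checkpointing, loss descent, and the
model/results interface."""

import dataclasses

import numpy as np
import pytest

from cyclereg.io_formats import RegistrationConfig
from cyclereg.model import CycleRegistration
from cyclereg.synthetic_data import make_dataset, make_pair, make_structural_pair
from cyclereg.training import (init_state, load_checkpoint, register_pair,
                               save_checkpoint, train, train_step)


@pytest.fixture(scope="module")
def small_pair():
    return make_structural_pair((12, 12, 12), n_structures=2, amplitude=1.0, seed=5)


@pytest.fixture(scope="module")
def func_pair():
    return make_pair(shape=(12, 12, 12), n_structures=2, amplitude=1.0, seed=5,
                     T=10, functional_factor=3)


def small_config(**over):
    cfg = RegistrationConfig(seed=0, kde_points=8, **over)
    return cfg.tiny()


class TestTrainStep:
    def test_deterministic_loss_sequences(self, small_pair):
        losses = []
        for _ in range(2):
            state = init_state(small_config(), seed=3)
            seq = [train_step((small_pair.fixed.data, small_pair.moving.data),
                              state).total for _ in range(2)]
            losses.append(seq)
        assert losses[0] == losses[1]        # bitwise equality

    def test_report_total_respects_weights(self, small_pair):
        state = init_state(small_config(), seed=0)
        r = train_step((small_pair.fixed.data, small_pair.moving.data), state)
        expected = (r.l_register_mri + r.alpha * r.l_register_fmri
                    + r.beta * r.l_cycle + r.gamma * r.l_identity)
        assert r.total == pytest.approx(expected, rel=1e-12)

    def test_functional_path_adds_fmri_terms(self, func_pair):
        state = init_state(small_config(), seed=0)
        r = train_step((func_pair.fixed.data, func_pair.moving.data,
                        func_pair.fixed_func.data, func_pair.moving_func.data),
                       state)
        assert r.l_register_fmri > 0.0
        assert "fmri_lfc_fwd" in r.breakdown

    def test_structural_only_pair_skips_functional(self, small_pair):
        state = init_state(small_config(), seed=0)
        r = train_step((small_pair.fixed.data, small_pair.moving.data), state)
        assert r.l_register_fmri == 0.0

    def test_mismatched_functional_grid_rejected(self, small_pair):
        state = init_state(small_config(), seed=0)
        bad = np.zeros((5, 5, 5, 8))
        with pytest.raises(ValueError, match="grid"):
            train_step((small_pair.fixed.data, small_pair.moving.data, bad, bad),
                       state)

    def test_strong_identity_weight_shrinks_fields(self, small_pair):
        # identical-pair input + dominant identity term drives |u| toward 0
        a = small_pair.fixed.data
        cfg = small_config(gamma=50.0)
        state = init_state(cfg, seed=1, learning_rate=1e-3)
        train_step((a, a), state)
        u0 = np.abs(state.g_a.forward(a, a).u).mean()
        for _ in range(30):
            train_step((a, a), state)
        u1 = np.abs(state.g_a.forward(a, a).u).mean()
        assert u1 <= u0

    def test_loss_decreases_under_training(self, small_pair):
        state = init_state(small_config(), seed=7, learning_rate=1e-3)
        first = train_step((small_pair.fixed.data, small_pair.moving.data), state)
        last = None
        for _ in range(40):
            last = train_step((small_pair.fixed.data, small_pair.moving.data), state)
        assert last.total < first.total


class TestTrainOverManifest:
    def test_zero_iterations_writes_initial_checkpoint(self, tmp_path):
        manifest = make_dataset(1, tmp_path / "data", shape=(12, 12, 12),
                                n_structures=2, T=10, with_functional=False, seed=0)
        cfg = dataclasses.replace(small_config(), max_iterations=0)
        ckpt = train(manifest, config=cfg, out_dir=tmp_path / "run")
        state = load_checkpoint(ckpt)
        assert state.iteration == 0

    def test_augmented_manifest_doubles_entries(self, tmp_path):
        manifest = make_dataset(1, tmp_path / "data", shape=(12, 12, 12),
                                n_structures=2, T=10, with_functional=False,
                                augment=True, seed=0)
        assert len(manifest["entries"]) == 2

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train({"entries": []})

    def test_training_writes_loss_log(self, tmp_path):
        manifest = make_dataset(1, tmp_path / "data", shape=(12, 12, 12),
                                n_structures=2, T=10, with_functional=False, seed=0)
        cfg = dataclasses.replace(small_config(), max_iterations=2)
        train(manifest, config=cfg, out_dir=tmp_path / "run")
        import pandas as pd

        log = pd.read_csv(tmp_path / "run" / "loss_log.csv")
        assert len(log) == 2
        assert "total" in log.columns


class TestCheckpoint:
    def test_round_trip_reproduces_forward(self, small_pair, tmp_path):
        state = init_state(small_config(), seed=2)
        train_step((small_pair.fixed.data, small_pair.moving.data), state)
        u_before = state.g_a.forward(small_pair.fixed, small_pair.moving).u
        path = tmp_path / "ckpt.npz"
        save_checkpoint(state, path)
        restored = load_checkpoint(path)
        u_after = restored.g_a.forward(small_pair.fixed, small_pair.moving).u
        np.testing.assert_array_equal(u_before, u_after)
        assert restored.iteration == 1


class TestRegisterPair:
    def test_warped_equals_warp_of_field(self, small_pair, tmp_path):
        state = init_state(small_config(), seed=0)
        warped, field = register_pair(small_pair.fixed, small_pair.moving,
                                      state=state)
        from cyclereg.spatial_transform import warp_volume

        np.testing.assert_array_equal(
            warped.data, warp_volume(small_pair.fixed, field).data)

    def test_functional_outputs_only_when_given(self, func_pair):
        state = init_state(small_config(), seed=0)
        out = register_pair(func_pair.fixed, func_pair.moving, state=state)
        assert len(out) == 2
        out = register_pair(func_pair.fixed, func_pair.moving,
                            moving_func=func_pair.fixed_func, state=state)
        assert len(out) == 4
        assert out[2].spatial_shape == func_pair.fixed_func.spatial_shape


class TestModelInterface:
    def test_fit_returns_results_with_history(self, small_pair):
        model = CycleRegistration.from_pair(small_pair, config=small_config())
        res = model.fit(max_iterations=2, seed=0)
        assert len(res.loss_history) == 2
        assert res.field_ab.shape == (12, 12, 12)
        assert "mean Dice" in res.summary()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            CycleRegistration(np.zeros((6, 6, 6)), np.zeros((8, 8, 8)))

    def test_endpoint_error_of_zero_field_equals_truth_magnitude(self, small_pair):
        model = CycleRegistration.from_pair(small_pair, config=small_config())
        state = init_state(small_config(), seed=0)
        for net in (state.g_a, state.g_b):
            for p in (net.head_w, net.head_b, net.head_coarse_w, net.head_coarse_b):
                p.data[:] = 0.0
        from cyclereg.model import CycleRegistrationResults

        res = CycleRegistrationResults(model, state)
        expected = float(small_pair.truth_field.magnitude().mean())
        assert res.endpoint_error(small_pair.truth_field) == pytest.approx(expected)
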