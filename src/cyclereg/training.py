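"""Bidirectional cycle-consistent training loop and the inference path.

Two registration networks are trained jointly: G_A produces the forward
field phi_AB = G_A(A, B) and G_B the reverse field phi_BA = G_B(B, A).
Each optimisation step evaluates

* the structural similarity + smoothness terms in both directions,
* (optionally) the functional similarity + LFC terms on the downsampled
  fields,
* the cycle terms through a second pass of each network on the deformed
  images, and
* the identity terms from self-registration,

combines them with the configured weights and applies one joint Adam
update to both networks.  All randomness flows from one seeded
generator; two runs with the same seed and data produce bitwise-equal
loss sequences.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from ._autodiff import Adam, Tensor
from .io_formats import (RegistrationConfig, TimeSeries4D, Volume3D,
                         read_series, read_volume)
from .lfc_features import sample_points
from .losses import (LossReport, l1_mean_t, lfc_distance_t, similarity_mse_t,
                     smoothness_t, total_loss)
from .registration_network import RegistrationNetwork
from .spatial_transform import (DeformationField, downsample_field,
                                downsample_field_tensor, warp_tensor,
                                warp_volume, warp_series)

__all__ = ["TrainState", "init_state", "train_step", "train",
           "register_pair", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainState:
    g_a: RegistrationNetwork
    g_b: RegistrationNetwork
    optimizer: Adam
    config: RegistrationConfig
    iteration: int = 0
    rng: np.random.Generator = None
    history: list = dc_field(default_factory=list)
    base_lr: float = 1e-4
    total_iterations: int | None = None


def init_state(config: RegistrationConfig | None = None, seed: int | None = None,
               learning_rate: float | None = None,
               total_iterations: int | None = None) -> TrainState:
    cfg = config or RegistrationConfig()
    seed = cfg.seed if seed is None else seed
    g_a = RegistrationNetwork(cfg, seed=seed)
    g_b = RegistrationNetwork(cfg, seed=seed + 1)
    lr = cfg.learning_rate if learning_rate is None else learning_rate
    opt = Adam(g_a.parameters() + g_b.parameters(), lr=lr)
    total = cfg.max_iterations if total_iterations is None else total_iterations
    return TrainState(g_a=g_a, g_b=g_b, optimizer=opt, config=cfg,
                      rng=np.random.default_rng(seed), base_lr=lr,
                      total_iterations=total)


def _scheduled_lr(state: TrainState) -> float:
    """Linear warmup over the first 10% of iterations, cosine decay to 10%
    of the base rate over the remainder."""
    total = max(state.total_iterations or 1, 1)
    warmup = max(int(0.1 * total), 1)
    t = state.iteration
    if t < warmup:
        return state.base_lr * (t + 1) / warmup
    frac = (t - warmup) / max(total - warmup, 1)
    frac = min(frac, 1.0)
    lo = 0.1 * state.base_lr
    return lo + 0.5 * (state.base_lr - lo) * (1.0 + np.cos(np.pi * frac))


def standardize(x: np.ndarray) -> np.ndarray:
    """Zero-mean / unit-variance intensities.

    The published loss weights (notably the smoothness lambda) presume
    intensity-normalised MRI; this is the model-side equivalent for
    arbitrary input scales.  Warped outputs are always resampled from
    the original intensities."""
    x = np.asarray(x, dtype=np.float64)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _clip_grad_norm(params, max_norm: float) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    total = np.sqrt(total)
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return total


def _functional_terms(x, y, u_ab, u_ba, cfg: RegistrationConfig, factor: int):
    """(fmri loss tensor, breakdown) for one pair of 4D series."""
    pts = sample_points(cfg.kde_points)
    if factor == 1:
        u_ab_c, u_ba_c = u_ab, u_ba
    else:
        u_ab_c = downsample_field_tensor(u_ab, factor)
        u_ba_c = downsample_field_tensor(u_ba, factor)
    x_t = Tensor(np.moveaxis(x, -1, 0))
    y_t = Tensor(np.moveaxis(y, -1, 0))
    breakdown = {}
    terms = None
    for tag, mov, fix, u in (("fwd", x_t, y_t, u_ab_c), ("rev", y_t, x_t, u_ba_c)):
        warped = warp_tensor(mov, u, leading=True)
        sim = similarity_mse_t(fix, warped)
        breakdown[f"fmri_similarity_{tag}"] = sim.item()
        term = sim
        if cfg.use_lfc_loss:
            w4 = warped.transpose(1, 2, 3, 0)
            f4 = fix.transpose(1, 2, 3, 0)
            lfc = lfc_distance_t(w4, f4, cfg.lfc_radius, pts, cfg.kde_bandwidth)
            breakdown[f"fmri_lfc_{tag}"] = lfc.item()
            term = term + lfc
        terms = term if terms is None else terms + term
    return terms, breakdown


def train_step(inputs, state: TrainState, config: RegistrationConfig | None = None) -> LossReport:
    """One joint optimisation step on a pair.

    `inputs` is (A, B) or (A, B, X, Y): structural ndarrays A, B and
    optional functional (D, H, W, T) ndarrays X, Y on the coarse grid.
    """
    cfg = config or state.config
    if len(inputs) == 2:
        a, b = inputs
        x = y = None
    else:
        a, b, x, y = inputs
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if cfg.standardize:
        a, b = standardize(a), standardize(b)
    a_t, b_t = Tensor(a), Tensor(b)
    g_a, g_b = state.g_a, state.g_b

    # first pass
    u_ab = g_a.forward_tensor(a_t, b_t)
    u_ba = g_b.forward_tensor(b_t, a_t)
    b_prime = warp_tensor(a_t, u_ab)
    a_prime = warp_tensor(b_t, u_ba)
    sim_fwd = similarity_mse_t(b_t, b_prime)
    sim_rev = similarity_mse_t(a_t, a_prime)
    smo_fwd = smoothness_t(u_ab)
    smo_rev = smoothness_t(u_ba)
    lam = cfg.smooth_weight
    l_mri = sim_fwd + lam * smo_fwd + sim_rev + lam * smo_rev
    breakdown = {
        "mri_similarity_fwd": sim_fwd.item(), "mri_similarity_rev": sim_rev.item(),
        "mri_smoothness_fwd": smo_fwd.item(), "mri_smoothness_rev": smo_rev.item(),
    }

    # functional path
    if x is not None and y is not None:
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        factor = a.shape[0] // x.shape[0]
        if tuple(n * factor for n in x.shape[:3]) != a.shape:
            raise ValueError(
                f"functional grid {x.shape[:3]} is not an integer divisor of the "
                f"structural grid {a.shape}")
        if cfg.standardize:
            x, y = standardize(x), standardize(y)
        l_fmri, fb = _functional_terms(x, y, u_ab, u_ba, cfg, factor)
        breakdown.update(fb)
    else:
        l_fmri = Tensor(0.0)

    # second pass: deformed images re-entered against the opposite original
    u_ba2 = g_b.forward_tensor(b_prime, a_t)
    u_ab2 = g_a.forward_tensor(a_prime, b_t)
    a_cycled = warp_tensor(b_prime, u_ba2)
    b_cycled = warp_tensor(a_prime, u_ab2)
    l_cycle = l1_mean_t(a_cycled, a_t) + l1_mean_t(b_cycled, b_t)

    # identity terms
    if cfg.identity_pairing == "crossed":
        u_id1 = g_a.forward_tensor(b_t, b_t)
        u_id2 = g_b.forward_tensor(a_t, a_t)
        l_identity = (similarity_mse_t(b_t, warp_tensor(b_t, u_id1))
                      + similarity_mse_t(a_t, warp_tensor(a_t, u_id2)))
    else:
        u_id1 = g_a.forward_tensor(a_t, a_t)
        u_id2 = g_b.forward_tensor(b_t, b_t)
        l_identity = (similarity_mse_t(a_t, warp_tensor(a_t, u_id1))
                      + similarity_mse_t(b_t, warp_tensor(b_t, u_id2)))

    loss = l_mri + cfg.alpha * l_fmri + cfg.beta * l_cycle + cfg.gamma * l_identity
    if not np.isfinite(loss.data):
        raise FloatingPointError(
            f"non-finite loss at iteration {state.iteration}: "
            f"mri={l_mri.item()}, fmri={l_fmri.item()}, "
            f"cycle={l_cycle.item()}, identity={l_identity.item()}")

    state.optimizer.zero_grad()
    loss.backward()
    if cfg.max_grad_norm > 0:
        _clip_grad_norm(state.optimizer.params, cfg.max_grad_norm)
    if cfg.lr_schedule == "warmup_cosine":
        state.optimizer.lr = _scheduled_lr(state)
    state.optimizer.step()
    state.iteration += 1

    report = total_loss(l_mri.item(), l_fmri.item(), l_cycle.item(),
                        l_identity.item(), alpha=cfg.alpha, beta=cfg.beta,
                        gamma=cfg.gamma, breakdown=breakdown)
    state.history.append(report)
    return report


# ---------------------------------------------------------------------------
# Dataset-level training
# ---------------------------------------------------------------------------

def _load_entry(entry: dict):
    a = read_volume(entry["fixed"]).data
    b = read_volume(entry["moving"]).data
    x = y = None
    if "fixed_func" in entry:
        x = read_series(entry["fixed_func"]).data
        y = read_series(entry["moving_func"]).data
    return a, b, x, y


def train(manifest, config: RegistrationConfig | None = None, out_dir=".",
          seed: int | None = None, learning_rate: float | None = None) -> str:
    """Train over a dataset manifest; returns the checkpoint path.

    `manifest` is the dict written by make_dataset (or a path to its
    JSON).  Pairs are visited in a seeded random order, one optimizer
    step per pair (batch size 1), up to config.max_iterations steps.
    Writes checkpoint.npz and a per-iteration loss log CSV to out_dir.
    """
    if isinstance(manifest, (str, os.PathLike)):
        with open(manifest) as fh:
            manifest = json.load(fh)
    entries = manifest["entries"]
    if not entries:
        raise ValueError("empty manifest")
    cfg = config or RegistrationConfig()
    state = init_state(cfg, seed=seed, learning_rate=learning_rate)
    os.makedirs(out_dir, exist_ok=True)
    pairs = [_load_entry(e) for e in entries]
    while state.iteration < cfg.max_iterations:
        order = state.rng.permutation(len(pairs))
        for idx in order:
            if state.iteration >= cfg.max_iterations:
                break
            a, b, x, y = pairs[idx]
            train_step((a, b, x, y) if x is not None else (a, b), state)
    ckpt = os.path.join(out_dir, "checkpoint.npz")
    save_checkpoint(state, ckpt)
    log_path = os.path.join(out_dir, "loss_log.csv")
    _write_loss_log(state.history, log_path)
    return ckpt


def _write_loss_log(history, path):
    import pandas as pd

    rows = [r.as_dict() for r in history]
    df = pd.DataFrame(rows)
    df.insert(0, "iteration", np.arange(1, len(rows) + 1))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(state: TrainState, path) -> None:
    arrays = {}
    for tag, net in (("ga", state.g_a), ("gb", state.g_b)):
        for i, arr in enumerate(net.state_arrays()):
            arrays[f"{tag}_{i}"] = arr
    arrays["iteration"] = np.array(state.iteration)
    arrays["config_yaml"] = np.frombuffer(
        yaml.safe_dump(state.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> TrainState:
    with np.load(path) as data:
        cfg_raw = yaml.safe_load(bytes(data["config_yaml"]).decode())
        cfg_raw.pop("config_version", None)
        cfg = RegistrationConfig(**cfg_raw)
        state = init_state(cfg, seed=cfg.seed)
        for tag, net in (("ga", state.g_a), ("gb", state.g_b)):
            n = len(net.parameters())
            net.load_state_arrays([data[f"{tag}_{i}"] for i in range(n)])
        state.iteration = int(data["iteration"])
    return state


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def register_pair(moving_struct: Volume3D, fixed_struct: Volume3D,
                  moving_func: TimeSeries4D | None = None,
                  checkpoint=None, state: TrainState | None = None):
    """Register one pair with a trained forward network (no optimisation).

    Returns (warped_struct, field) or, when a functional series is given,
    (warped_struct, field, warped_func, field_coarse).
    """
    if state is None:
        if checkpoint is None:
            raise ValueError("need a checkpoint or a TrainState")
        state = load_checkpoint(checkpoint)
    if state.config.standardize:
        mv = standardize(moving_struct.data)
        fx = standardize(fixed_struct.data)
        u = state.g_a.forward_tensor(Tensor(mv), Tensor(fx))
        field = DeformationField(u.data, spacing=moving_struct.spacing)
    else:
        field = state.g_a.forward(moving_struct, fixed_struct)
    warped = warp_volume(moving_struct, field)
    if moving_func is None:
        return warped, field
    factor = moving_struct.shape[0] // moving_func.spatial_shape[0]
    if tuple(n * factor for n in moving_func.spatial_shape) != tuple(moving_struct.shape):
        raise ValueError(
            f"functional grid {moving_func.spatial_shape} must divide the "
            f"structural grid {tuple(moving_struct.shape)} by an integer factor")
    field_coarse = downsample_field(field, factor=factor)
    warped_func = warp_series(moving_func, field_coarse)
    return warped, field, warped_func, field_coarse
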