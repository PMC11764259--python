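"""U-Net-like registration network with a hierarchical shifted-window
attention encoder and a convolutional decoder.

The two input volumes (moving, fixed) are stacked as a 2-channel image,
cut into non-overlapping patches and embedded; four encoder stages of
window / shifted-window multi-head self-attention block pairs (depths
2, 2, 4, 2 by default) build hierarchical features, patch merging halving
the resolution between stages.  A convolutional decoder with skip
connections restores full resolution and a 1x1x1 head emits the dense
3-channel displacement field.  Head weights are initialised near zero so
an untrained network emits a near-identity deformation.

Window attention follows Attention(Q, K, V) = softmax(Q K^T / sqrt(d) + B) V
with a learnable relative-position bias table B of size
(2 Mx - 1)(2 My - 1)(2 Mz - 1) per head.  The shifted variant displaces
the window grid by floor(M/2) per axis, realised as a cyclic shift plus
an attention mask that keeps tokens from different pre-shift regions
(and zero-padded positions) from attending to each other.
"""

from __future__ import annotations

import math

import numpy as np

from ._autodiff import Module, Tensor, as_tensor, concatenate, conv3d
from .io_formats import RegistrationConfig, Volume3D
from .spatial_transform import DeformationField, sample_trilinear

__all__ = [
    "partition_windows", "merge_windows", "count_shifted_windows",
    "window_attention", "RegistrationNetwork", "WindowConfig",
]


# ---------------------------------------------------------------------------
# Window arithmetic
# ---------------------------------------------------------------------------

def _padded_dims(shape, M):
    return tuple(int(math.ceil(n / m) * m) for n, m in zip(shape, M))


def partition_windows(feat: np.ndarray, M):
    """Split a (C, D, H, W) feature map into non-overlapping windows.

    The spatial extents are zero-padded up to multiples of the window
    size first.  Returns (windows, count) with windows shaped
    (count, C, Mx, My, Mz); count = prod(ceil(dim / M)).
    """
    feat = np.asarray(feat)
    if feat.ndim != 4:
        raise ValueError("feature map must be (C, D, H, W)")
    M = tuple(int(m) for m in M)
    C = feat.shape[0]
    dims = feat.shape[1:]
    pd = _padded_dims(dims, M)
    if pd != dims:
        feat = np.pad(feat, ((0, 0),) + tuple((0, p - n) for n, p in zip(dims, pd)))
    nd, nh, nw = (pd[i] // M[i] for i in range(3))
    win = feat.reshape(C, nd, M[0], nh, M[1], nw, M[2])
    win = win.transpose(1, 3, 5, 0, 2, 4, 6).reshape(nd * nh * nw, C, *M)
    return win, nd * nh * nw


def merge_windows(windows: np.ndarray, M, shape):
    """Inverse of :func:`partition_windows` (crops any padding)."""
    M = tuple(int(m) for m in M)
    pd = _padded_dims(shape, M)
    nd, nh, nw = (pd[i] // M[i] for i in range(3))
    C = windows.shape[1]
    feat = windows.reshape(nd, nh, nw, C, *M)
    feat = feat.transpose(3, 0, 4, 1, 5, 2, 6).reshape(C, *pd)
    return feat[:, :shape[0], :shape[1], :shape[2]]


def count_shifted_windows(shape, M) -> int:
    """Number of distinct window regions after shifting the partition grid
    by floor(M/2) per axis (counted before any cyclic-shift batching)."""
    M = tuple(int(m) for m in M)
    pd = _padded_dims(shape, M)
    total = 1
    for n, m in zip(pd, M):
        s = m // 2
        if s == 0:
            regions = n // m
        else:
            regions = int(math.ceil((n - s) / m)) + 1
        total *= regions
    return total


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------

def window_attention(q, k, v, bias=None, mask=None):
    """softmax(Q K^T / sqrt(d) + B) V within a window.

    q, k, v: (..., N, d) arrays or tensors; bias broadcastable to the
    (..., N, N) logits; mask (additive, -inf-style) likewise.
    """
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    if q.shape != k.shape or k.shape[:-1] != v.shape[:-1]:
        raise ValueError("Q, K, V shape mismatch")
    d = q.shape[-1]
    logits = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * (1.0 / math.sqrt(d))
    if bias is not None:
        logits = logits + as_tensor(bias)
    if mask is not None:
        logits = logits + as_tensor(mask)
    attn = logits.softmax(axis=-1)
    return attn @ v


class WindowConfig:
    """Window geometry + attention dimensions for one encoder stage."""

    def __init__(self, M, heads: int, dim: int):
        self.M = tuple(int(m) for m in M)
        if any(m < 1 for m in self.M):
            raise ValueError("window extents must be >= 1")
        self.heads = heads
        self.dim = dim
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.head_dim = dim // heads
        self.bias_size = int(np.prod([2 * m - 1 for m in self.M]))

    def relative_index(self) -> np.ndarray:
        """(N, N) indices into the flattened bias table."""
        coords = np.stack(np.meshgrid(*[np.arange(m) for m in self.M],
                                      indexing="ij"), axis=0).reshape(3, -1)
        rel = coords[:, :, None] - coords[:, None, :]
        for d in range(3):
            rel[d] += self.M[d] - 1
        idx = (rel[0] * (2 * self.M[1] - 1) + rel[1]) * (2 * self.M[2] - 1) + rel[2]
        return idx.astype(np.intp)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _trunc_normal(rng, shape, sd=0.02):
    w = rng.standard_normal(shape) * sd
    return np.clip(w, -2 * sd, 2 * sd)


class Linear(Module):
    def __init__(self, n_in, n_out, rng, sd=0.02):
        self.w = Tensor(_trunc_normal(rng, (n_in, n_out), sd), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        self.g = Tensor(np.ones(dim), requires_grad=True)
        self.b = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.g + self.b


class Mlp(Module):
    def __init__(self, dim, ratio, rng):
        hidden = int(dim * ratio)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class WindowAttentionLayer(Module):
    """Multi-head self-attention inside (possibly shifted) local windows."""

    def __init__(self, cfg: WindowConfig, rng):
        self.cfg = cfg
        d = cfg.dim
        self.qkv = Linear(d, 3 * d, rng)
        self.proj = Linear(d, d, rng)
        self.bias_table = Tensor(_trunc_normal(rng, (cfg.heads, cfg.bias_size)),
                                 requires_grad=True)
        self._rel_idx = cfg.relative_index()

    def __call__(self, windows: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """windows: (nw, N, C) token windows; mask: (nw, N, N) additive."""
        nw, N, C = windows.shape
        h, hd = self.cfg.heads, self.cfg.head_dim
        qkv = self.qkv(windows)                       # (nw, N, 3C)
        qkv = qkv.reshape(nw, N, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]              # (nw, h, N, hd)
        bias = self.bias_table[:, self._rel_idx]      # (h, N, N)
        m = None
        if mask is not None:
            m = mask[:, None, :, :]                   # (nw, 1, N, N)
        out = window_attention(q, k, v, bias=bias, mask=m)
        out = out.transpose(0, 2, 1, 3).reshape(nw, N, C)
        return self.proj(out)


# ---------------------------------------------------------------------------
# Token-grid window helpers (Tensor layout (D, H, W, C))
# ---------------------------------------------------------------------------

def _partition_tokens(x: Tensor, M):
    D, H, W, C = x.shape
    pd = _padded_dims((D, H, W), M)
    if pd != (D, H, W):
        x = x.pad(tuple((0, p - n) for n, p in zip((D, H, W), pd)) + ((0, 0),))
    nd, nh, nw = (pd[i] // M[i] for i in range(3))
    x = x.reshape(nd, M[0], nh, M[1], nw, M[2], C)
    x = x.transpose(0, 2, 4, 1, 3, 5, 6)
    return x.reshape(nd * nh * nw, M[0] * M[1] * M[2], C), pd


def _merge_tokens(win: Tensor, M, pd, shape):
    nd, nh, nw = (pd[i] // M[i] for i in range(3))
    C = win.shape[-1]
    x = win.reshape(nd, nh, nw, M[0], M[1], M[2], C)
    x = x.transpose(0, 3, 1, 4, 2, 5, 6).reshape(*pd, C)
    return x[:shape[0], :shape[1], :shape[2], :]


def _region_map(shape, M, shift, pad_to):
    """Region IDs on the padded grid; padded voxels get a sentinel ID."""
    rid = np.zeros(pad_to, dtype=np.int64)
    weight = 1
    for d in range(3):
        ids = np.zeros(pad_to[d], dtype=np.int64)
        m, s = M[d], shift[d]
        if s > 0:
            cnt = 0
            for sl in (slice(0, pad_to[d] - m), slice(pad_to[d] - m, pad_to[d] - s),
                       slice(pad_to[d] - s, pad_to[d])):
                ids[sl] = cnt
                cnt += 1
        shp = [1, 1, 1]
        shp[d] = -1
        rid += weight * ids.reshape(shp)
        weight *= 8
    for d in range(3):
        if pad_to[d] > shape[d]:
            sl = [slice(None)] * 3
            sl[d] = slice(shape[d], None)
            rid[tuple(sl)] = -1 - d  # padding: isolated sentinel regions
    return rid


def _attention_mask(shape, M, shift):
    pd = _padded_dims(shape, M)
    rid = _region_map(shape, M, shift, pd)
    win, _ = _partition_tokens(Tensor(rid.astype(np.float64)[..., None]), M)
    ids = win.data[..., 0]                            # (nw, N)
    same = ids[:, :, None] == ids[:, None, :]
    if same.all():
        return None
    return np.where(same, 0.0, -1e9)


class SwinBlock(Module):
    """One attention block: LN -> (S)W-MSA -> residual; LN -> MLP -> residual."""

    def __init__(self, dim, cfg: WindowConfig, shifted: bool, mlp_ratio, rng):
        self.cfg = cfg
        self.shifted = shifted
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttentionLayer(cfg, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, mlp_ratio, rng)

    def __call__(self, x: Tensor) -> Tensor:
        D, H, W, C = x.shape
        # windows are clamped to the grid on small feature maps; the bias
        # table of the full window is shared through a sub-gather
        M = tuple(min(m, s) for m, s in zip(self.cfg.M, (D, H, W)))
        shift = tuple(m // 2 for m in M) if self.shifted else (0, 0, 0)
        h = self.norm1(x)
        if any(shift):
            h = h.roll(tuple(-s for s in shift), axis=(0, 1, 2))
        mask = _attention_mask((D, H, W), M, shift)
        win, pd = _partition_tokens(h, M)
        out = self._attend(win, M, mask)
        h = _merge_tokens(out, M, pd, (D, H, W))
        if any(shift):
            h = h.roll(shift, axis=(0, 1, 2))
        x = x + h
        return x + self.mlp(self.norm2(x))

    def _attend(self, win: Tensor, M, mask):
        layer = self.attn
        if M == self.cfg.M:
            return layer(win, mask=mask)
        # clamped window: gather the matching sub-table of the relative bias
        sub = WindowConfig(M, self.cfg.heads, self.cfg.dim)
        nw, N, C = win.shape
        h, hd = sub.heads, sub.head_dim
        qkv = layer.qkv(win).reshape(nw, N, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]
        # map clamped relative offsets into the full-size bias table
        coords = np.stack(np.meshgrid(*[np.arange(m) for m in M], indexing="ij"),
                          axis=0).reshape(3, -1)
        rel = coords[:, :, None] - coords[:, None, :]
        full = self.cfg.M
        for d in range(3):
            rel[d] += full[d] - 1
        idx = (rel[0] * (2 * full[1] - 1) + rel[1]) * (2 * full[2] - 1) + rel[2]
        bias = layer.bias_table[:, idx.astype(np.intp)]
        m = mask[:, None, :, :] if mask is not None else None
        out = window_attention(q, k, v, bias=bias, mask=m)
        return layer.proj(out.transpose(0, 2, 1, 3).reshape(nw, N, C))


class PatchMerging(Module):
    """2x spatial reduction: 8-neighbour concatenation + linear projection."""

    def __init__(self, dim, rng):
        self.norm = LayerNorm(8 * dim)
        self.reduce = Linear(8 * dim, 2 * dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        D, H, W, C = x.shape
        # replicate the border slice on odd extents (constancy-preserving)
        for axis, n in enumerate((D, H, W)):
            if n % 2:
                sl = [slice(None)] * 4
                sl[axis] = slice(n - 1, n)
                x = concatenate([x, x[tuple(sl)]], axis=axis)
        D, H, W = D + D % 2, H + H % 2, W + W % 2
        parts = [x[a::2, b::2, c::2, :] for a in range(2) for b in range(2) for c in range(2)]
        x = concatenate(parts, axis=-1)
        return self.reduce(self.norm(x))


class PatchEmbed(Module):
    """Space-to-depth patch cut followed by a linear embedding."""

    def __init__(self, patch, in_ch, dim, rng):
        self.patch = patch
        self.proj = Linear(in_ch * patch ** 3, dim, rng)
        self.norm = LayerNorm(dim)

    def __call__(self, x: Tensor) -> Tensor:
        C, D, H, W = x.shape
        p = self.patch
        x = x.reshape(C, D // p, p, H // p, p, W // p, p)
        x = x.transpose(1, 3, 5, 0, 2, 4, 6).reshape(D // p, H // p, W // p, C * p ** 3)
        return self.norm(self.proj(x))


class ConvBlock(Module):
    def __init__(self, c_in, c_out, rng, k=3):
        fan = c_in * k ** 3
        sd = math.sqrt(2.0 / fan)
        self.w = Tensor(rng.standard_normal((c_out, c_in, k, k, k)) * sd,
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        # edge padding keeps constant feature maps spatially constant
        return conv3d(x, self.w, self.b, padding=self.pad,
                      pad_mode="edge").leaky_relu(0.2)


def _resize(x: Tensor, out_shape):
    """Trilinear resize of a (C, D, H, W) tensor to spatial out_shape."""
    in_shape = x.shape[1:]
    if tuple(in_shape) == tuple(out_shape):
        return x
    axes = []
    for n_in, n_out in zip(in_shape, out_shape):
        axes.append(np.clip((np.arange(n_out) + 0.5) * n_in / n_out - 0.5, 0, n_in - 1))
    coords = np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)
    return sample_trilinear(x, Tensor(coords), leading=True)


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

class RegistrationNetwork(Module):
    """(moving, fixed) -> dense displacement field, same grid as the inputs."""

    def __init__(self, config: RegistrationConfig | None = None, seed: int = 0):
        cfg = config or RegistrationConfig()
        self.config = cfg
        rng = np.random.default_rng(seed)
        p = cfg.patch_size
        C = cfg.embed_dim
        self.patch_embed = PatchEmbed(p, 2, C, rng)
        self.stages = []
        self.mergers = []
        dims = [C * 2 ** i for i in range(4)]
        for i, depth in enumerate(cfg.block_depths):
            wc = WindowConfig(cfg.window_size, cfg.heads[i], dims[i])
            blocks = []
            for j in range(depth // 2):
                blocks.append(SwinBlock(dims[i], wc, shifted=False,
                                        mlp_ratio=cfg.mlp_ratio, rng=rng))
                blocks.append(SwinBlock(dims[i], wc, shifted=True,
                                        mlp_ratio=cfg.mlp_ratio, rng=rng))
            self.stages.append(blocks)
            if i < 3:
                self.mergers.append(PatchMerging(dims[i], rng))
        # decoder: deepest -> shallowest, skip concatenation at each level
        self.dec = []
        for i in (2, 1, 0):
            self.dec.append(ConvBlock(dims[i + 1] + dims[i], dims[i], rng))
        c_last = max(dims[0], 16)
        self.dec_full = ConvBlock(dims[0] + 2, c_last, rng)
        # multi-scale field head: a coarse head at the patch-embedding
        # resolution captures the smooth bulk of the deformation, a
        # full-resolution head refines it; both start near zero
        self.head_coarse_w = Tensor(rng.standard_normal((3, dims[0], 1, 1, 1)) * 1e-5,
                                    requires_grad=True)
        self.head_coarse_b = Tensor(np.zeros(3), requires_grad=True)
        self.head_w = Tensor(rng.standard_normal((3, c_last, 1, 1, 1)) * 1e-5,
                             requires_grad=True)
        self.head_b = Tensor(np.zeros(3), requires_grad=True)

    # -- forward ----------------------------------------------------------
    def forward_tensor(self, moving: Tensor, fixed: Tensor) -> Tensor:
        """Differentiable forward; inputs (D, H, W) tensors, output (3, D, H, W)."""
        moving, fixed = as_tensor(moving), as_tensor(fixed)
        if moving.shape != fixed.shape:
            raise ValueError("moving and fixed must share a grid")
        shape = moving.shape
        p = self.config.patch_size
        if any(n % p for n in shape):
            need = tuple(int(math.ceil(n / p) * p) for n in shape)
            raise ValueError(
                f"input shape {shape} not divisible by patch size {p}; "
                f"pad to {need} first")
        x2 = concatenate([moving.reshape(1, *shape), fixed.reshape(1, *shape)], axis=0)
        z = self.patch_embed(x2)
        skips = []
        for i, blocks in enumerate(self.stages):
            for blk in blocks:
                z = blk(z)
            skips.append(z)
            if i < 3:
                z = self.mergers[i](z)
        feat = skips[-1].transpose(3, 0, 1, 2)          # (C, d, h, w)
        for conv, skip in zip(self.dec, (skips[2], skips[1], skips[0])):
            s = skip.transpose(3, 0, 1, 2)
            feat = _resize(feat, s.shape[1:])
            feat = conv(concatenate([feat, s], axis=0))
        u_coarse = conv3d(feat, self.head_coarse_w, self.head_coarse_b, padding=0)
        # coarse displacements are in coarse-voxel units; rescale on upsampling
        u_coarse = _resize(u_coarse, shape) * (shape[0] / feat.shape[1])
        feat = _resize(feat, shape)
        feat = self.dec_full(concatenate([feat, x2], axis=0))
        u = conv3d(feat, self.head_w, self.head_b, padding=0) + u_coarse
        # bounded displacement: saturate smoothly at a fraction of the
        # field of view; displacements beyond that are meaningless and,
        # unbounded, would park the sampler in the clamped border region
        # where image gradients vanish
        cap = self.config.displacement_cap_fraction * min(shape)
        if cap > 0:
            u = (u * (1.0 / cap)).tanh() * cap
        return u

    def forward(self, moving, fixed) -> DeformationField:
        """Inference: numpy in, DeformationField out."""
        mv = moving.data if isinstance(moving, Volume3D) else np.asarray(moving)
        fx = fixed.data if isinstance(fixed, Volume3D) else np.asarray(fixed)
        u = self.forward_tensor(Tensor(mv), Tensor(fx))
        spacing = moving.spacing if isinstance(moving, Volume3D) else (1.0, 1.0, 1.0)
        return DeformationField(u.data, spacing=spacing)

    __call__ = forward
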