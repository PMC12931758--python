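"""Contract-level neural components of the toolkit.

Three building blocks, all running on the package's numpy autodiff engine:

* **Embedder** — one-hot sequence → sequence representation (L × d_s) via a
  learned linear map plus a learned absolute positional table (initialized
  to zero), and pair representation (L × L × d_z) formed by adding two
  independent projections of the sequence representation along rows and
  columns, plus a clipped relative-position embedding.
* **TransformerBlock** — row attention with a pair-bias term projected from
  the pair representation, a transition MLP, then pair updates: outer product
  mean, triangle multiplicative updates (outgoing/incoming), optional
  triangle attention (starting/ending node; the language-model variant omits
  these), and a pair transition.  An attention-dropout operation can zero a
  fraction of attention weights during training and renormalizes the rows.
* **DenoisingStructureModule (DRSM)** — iterative invariant-point-attention
  updates of per-nucleotide rigid frames from a black-hole start (identity
  rotation, zero translation); during training the start is perturbed with
  ``perturb_frames(·, w=0.1, sigma=0.1)``.  Heads: a 40-bin distogram over
  the three atom-pair channels (P–P, C4'–C4', N–N) and a non-negative
  pair-error map.

Desk-scale defaults (2 blocks, d_s=32, d_z=16) are config-driven; the
full-scale dimensions are expressible through the same config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from ._nn import Module, Linear, LayerNorm
from .geometry import FrameSet, symmetric_orthogonalize, perturb_frames

__all__ = [
    "NetworkConfig",
    "SequenceRepresentation",
    "PairRepresentation",
    "Distogram",
    "PairErrorMap",
    "Embedder",
    "TransformerBlock",
    "DenoisingStructureModule",
    "RCLMModel",
    "FoldingModel",
    "attention_dropout",
    "embed_sequence",
    "transformer_block",
    "drsm_forward",
    "save_model",
    "load_model",
]

ALPHABET = "ACGU"
MASK_INDEX = 4
N_DIST_BINS = 40
DIST_CHANNELS = 3  # P-P, C4'-C4', N-N


# ---------------------------------------------------------------------------
# configuration and contract types
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Hyper-parameters for embedder, transformer stack and DRSM."""

    d_s: int = 32
    d_z: int = 16
    n_blocks: int = 2
    n_heads: int = 4
    pair_heads: int = 2
    variant: str = "rclm"          # "rclm" (no triangle attention) or "full"
    attn_dropout: float = 0.0      # 0.25 in the folding stack
    transition_factor: int = 4
    opm_dim: int = 8
    rel_pos_clip: int = 64         # covers full-span pairs at desk-scale lengths
    max_len: int = 512             # capacity of the absolute positional table
    in_dim: int = 5                # 4 nucleotides + mask symbol (4 for folding)
    # DRSM
    ipa_iterations: int = 2
    ipa_heads: int = 4
    ipa_query_points: int = 4
    denoise_w: float = 0.1
    denoise_sigma: float = 0.1
    zero_init_residuals: bool = True   # zero the last linear of each residual branch
    gate_bias: float = 1.0             # sigmoid gates start mostly open
    dtype: str = "float32"

    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclass
class SequenceRepresentation:
    values: np.ndarray  # (L, d_s)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or not np.isfinite(self.values).all():
            raise ValueError("sequence representation must be a finite L x d_s array")


@dataclass
class PairRepresentation:
    values: np.ndarray  # (L, L, d_z)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1] \
                or not np.isfinite(self.values).all():
            raise ValueError("pair representation must be a finite L x L x d_z array")


@dataclass
class Distogram:
    """Binned distance probabilities, shape (3, L, L, 40); slices sum to 1."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        p = self.probs
        if p.ndim != 4 or p.shape[0] != DIST_CHANNELS or p.shape[3] != N_DIST_BINS \
                or p.shape[1] != p.shape[2]:
            raise ValueError(f"distogram must have shape (3, L, L, {N_DIST_BINS})")
        if (p < -1e-9).any() or not np.allclose(p.sum(axis=-1), 1.0, atol=1e-6):
            raise ValueError("each distogram slice must be a probability vector")

    @property
    def length(self):
        return self.probs.shape[1]


@dataclass
class PairErrorMap:
    """Non-negative per-pair weights (predicted pairwise error scores)."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("pair error map must be a square L x L array")
        if not np.isfinite(w).all() or (w < 0).any():
            raise ValueError("pair error map must be finite and non-negative")


def one_hot(indices: np.ndarray, depth: int, dtype=np.float32) -> np.ndarray:
    out = np.zeros(indices.shape + (depth,), dtype=dtype)
    np.put_along_axis(out, indices[..., None], 1.0, axis=-1)
    return out


def encode_sequence(symbols: str, n_classes: int = 5) -> np.ndarray:
    """Symbols (with optional mask placeholder 'N') → one-hot (L, n_classes)."""
    lookup = {c: i for i, c in enumerate(ALPHABET)}
    lookup["N"] = MASK_INDEX
    idx = np.array([lookup[c] for c in symbols], dtype=np.int64)
    if n_classes == 4 and (idx == MASK_INDEX).any():
        raise ValueError("mask symbol not representable in a 4-class encoding")
    return one_hot(idx, n_classes)


# ---------------------------------------------------------------------------
# attention dropout (standalone operation)
# ---------------------------------------------------------------------------

def attention_dropout(weights, rate: float, seed: int | None = None,
                      training: bool = False, rng: np.random.Generator | None = None):
    """Randomly zero attention weights and renormalize the rows.

    In training mode each weight is independently zeroed with probability
    ``rate`` and each row is rescaled to sum to one again; rows losing all
    mass fall back to the unmasked row.  In inference mode this is the
    identity.  Accepts numpy arrays or autodiff tensors (gradients flow
    through the surviving weights).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
    if not training or rate == 0.0:
        return weights
    if rng is None:
        rng = np.random.default_rng(seed)
    w = weights if isinstance(weights, Tensor) else Tensor(np.asarray(weights))
    keep = (rng.random(w.data.shape) >= rate).astype(w.data.dtype)
    masked = w * keep
    row_sum = masked.sum(axis=-1, keepdims=True)
    dead = row_sum.data <= 0.0
    safe = ag.where(dead, w, masked / ag.maximum(row_sum, np.finfo(w.data.dtype).tiny))
    return safe if isinstance(weights, Tensor) else safe.data


# ---------------------------------------------------------------------------
# embedder
# ---------------------------------------------------------------------------

class Embedder(Module):
    """One-hot → (sequence rep, pair rep).

    The sequence representation is a learned linear map of the one-hot input
    plus a learned absolute positional embedding (initialized to zero, so the
    embedding is position-free at initialization).  The pair representation
    entry (i, j) is ``row_proj(s_i) + col_proj(s_j) + rel_pos(j - i)`` with
    the relative offset clipped to ±``rel_pos_clip``.
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        dt = cfg.np_dtype()
        self.cfg = cfg
        self.seq_proj = Linear(cfg.in_dim, cfg.d_s, rng, dtype=dt)
        self.abs_pos = Tensor.param(np.zeros((cfg.max_len, cfg.d_s), dtype=dt))
        self.row_proj = Linear(cfg.d_s, cfg.d_z, rng, dtype=dt)
        self.col_proj = Linear(cfg.d_s, cfg.d_z, rng, dtype=dt)
        n_rel = 2 * cfg.rel_pos_clip + 1
        self.rel_pos = Tensor.param(rng.normal(0.0, 0.02, size=(n_rel, cfg.d_z)).astype(dt))

    def __call__(self, x: Tensor):
        """x: (B, L, in_dim) one-hot; returns s (B, L, d_s), z (B, L, L, d_z)."""
        if x.shape[-2] < 1:
            raise ValueError("cannot embed an empty sequence")
        if x.shape[-2] > self.cfg.max_len:
            raise ValueError(f"sequence longer than positional capacity {self.cfg.max_len}")
        s = self.seq_proj(x) + self.abs_pos[np.arange(x.shape[-2])]
        row = self.row_proj(s)  # (B, L, d_z)
        col = self.col_proj(s)
        L = s.shape[-2]
        offs = np.clip(np.arange(L)[None, :] - np.arange(L)[:, None],
                       -self.cfg.rel_pos_clip, self.cfg.rel_pos_clip) + self.cfg.rel_pos_clip
        B = s.shape[0]
        z = row.reshape(B, L, 1, self.cfg.d_z) + col.reshape(B, 1, L, self.cfg.d_z) \
            + self.rel_pos[offs]
        return s, z


def embed_sequence(embedder: Embedder, seq_or_onehot) -> tuple[SequenceRepresentation, PairRepresentation]:
    """Contract wrapper: run the embedder on one sequence, return typed reps."""
    if isinstance(seq_or_onehot, str):
        x = encode_sequence(seq_or_onehot, embedder.cfg.in_dim)
    else:
        x = np.asarray(seq_or_onehot, dtype=embedder.cfg.np_dtype())
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("expected a non-empty (L, in_dim) one-hot array")
    with ag.no_grad():
        s, z = embedder(Tensor(x[None]))
    return SequenceRepresentation(s.data[0]), PairRepresentation(z.data[0])


# ---------------------------------------------------------------------------
# transformer block
# ---------------------------------------------------------------------------

class PairBiasAttention(Module):
    """Multi-head attention over the sequence axis with an additive bias
    projected from the pair representation."""

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        dt = cfg.np_dtype()
        self.h = cfg.n_heads
        self.dh = cfg.d_s // cfg.n_heads
        self.q = Linear(cfg.d_s, cfg.d_s, rng, bias=False, dtype=dt)
        self.k = Linear(cfg.d_s, cfg.d_s, rng, bias=False, dtype=dt)
        self.v = Linear(cfg.d_s, cfg.d_s, rng, bias=False, dtype=dt)
        self.pair_bias = Linear(cfg.d_z, cfg.n_heads, rng, bias=False, dtype=dt)
        out_scale = 0.0 if cfg.zero_init_residuals else None
        self.out = Linear(cfg.d_s, cfg.d_s, rng, scale=out_scale, dtype=dt)
        self.dropout_rate = cfg.attn_dropout

    def __call__(self, s: Tensor, z: Tensor, training=False, rng=None):
        B, L, d = s.shape
        h, dh = self.h, self.dh
        q = self.q(s).reshape(B, L, h, dh)
        k = self.k(s).reshape(B, L, h, dh)
        v = self.v(s).reshape(B, L, h, dh)
        logits = ag.einsum("bihd,bjhd->bhij", q, k) * (1.0 / np.sqrt(dh))
        bias = self.pair_bias(z)                      # (B, L, L, h)
        logits = logits + bias.transpose(0, 3, 1, 2)  # (B, h, L, L)
        att = ag.softmax(logits, axis=-1)
        att = attention_dropout(att, self.dropout_rate, training=training, rng=rng)
        o = ag.einsum("bhij,bjhd->bihd", att, v).reshape(B, L, h * dh)
        return self.out(o)


class Transition(Module):
    def __init__(self, dim, factor, rng, dtype, out_scale=None):
        super().__init__()
        self.fc1 = Linear(dim, dim * factor, rng, dtype=dtype)
        self.fc2 = Linear(dim * factor, dim, rng, scale=out_scale, dtype=dtype)

    def __call__(self, x):
        return self.fc2(self.fc1(x).relu())


class OuterProductMean(Module):
    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        dt = cfg.np_dtype()
        c = cfg.opm_dim
        self.a = Linear(cfg.d_s, c, rng, dtype=dt)
        self.b = Linear(cfg.d_s, c, rng, dtype=dt)
        self.out = Linear(c * c, cfg.d_z, rng,
                          scale=0.0 if cfg.zero_init_residuals else None, dtype=dt)

    def __call__(self, s):
        a = self.a(s)  # (B, L, c)
        b = self.b(s)
        B, L, c = a.shape
        outer = ag.einsum("bic,bjd->bijcd", a, b).reshape(B, L, L, c * c)
        return self.out(outer)


class TriangleMultiplication(Module):
    """Gated triangle multiplicative update ('outgoing' or 'incoming')."""

    def __init__(self, cfg: NetworkConfig, rng, direction: str):
        super().__init__()
        dt = cfg.np_dtype()
        d = cfg.d_z
        self.direction = direction
        self.proj_a = Linear(d, d, rng, dtype=dt)
        self.gate_a = Linear(d, d, rng, dtype=dt)
        self.proj_b = Linear(d, d, rng, dtype=dt)
        self.gate_b = Linear(d, d, rng, dtype=dt)
        self.norm_out = LayerNorm(d, dtype=dt)
        self.out = Linear(d, d, rng,
                          scale=0.0 if cfg.zero_init_residuals else None, dtype=dt)
        self.gate_out = Linear(d, d, rng, dtype=dt)
        for gate in (self.gate_a, self.gate_b, self.gate_out):
            gate.bias.data[:] = cfg.gate_bias

    def __call__(self, z):
        a = self.proj_a(z) * self.gate_a(z).sigmoid()
        b = self.proj_b(z) * self.gate_b(z).sigmoid()
        if self.direction == "outgoing":
            prod = ag.einsum("bikc,bjkc->bijc", a, b)
        else:
            prod = ag.einsum("bkic,bkjc->bijc", a, b)
        return self.out(self.norm_out(prod)) * self.gate_out(z).sigmoid()


class TriangleAttention(Module):
    """Triangle attention around the starting or ending node."""

    def __init__(self, cfg: NetworkConfig, rng, node: str):
        super().__init__()
        dt = cfg.np_dtype()
        d = cfg.d_z
        self.node = node
        self.h = cfg.pair_heads
        self.dh = d // cfg.pair_heads
        self.q = Linear(d, d, rng, bias=False, dtype=dt)
        self.k = Linear(d, d, rng, bias=False, dtype=dt)
        self.v = Linear(d, d, rng, bias=False, dtype=dt)
        self.bias = Linear(d, cfg.pair_heads, rng, bias=False, dtype=dt)
        self.out = Linear(d, d, rng,
                          scale=0.0 if cfg.zero_init_residuals else None, dtype=dt)

    def __call__(self, z):
        if self.node == "ending":
            z_in = z.transpose(0, 2, 1, 3)
        else:
            z_in = z
        B, L, _, d = z_in.shape
        h, dh = self.h, self.dh
        q = self.q(z_in).reshape(B, L, L, h, dh)
        k = self.k(z_in).reshape(B, L, L, h, dh)
        v = self.v(z_in).reshape(B, L, L, h, dh)
        logits = ag.einsum("bijhd,bikhd->bhijk", q, k) * (1.0 / np.sqrt(dh))
        bias = self.bias(z_in)  # (B, L, L, h) indexed (j, k)
        logits = logits + bias.transpose(0, 3, 1, 2).reshape(B, h, 1, L, L)
        att = ag.softmax(logits, axis=-1)
        o = ag.einsum("bhijk,bikhd->bijhd", att, v).reshape(B, L, L, h * dh)
        out = self.out(o)
        if self.node == "ending":
            out = out.transpose(0, 2, 1, 3)
        return out


class TransformerBlock(Module):
    """One RNA transformer block; ``variant='rclm'`` omits triangle attention."""

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        dt = cfg.np_dtype()
        self.cfg = cfg
        self.norm_s_att = LayerNorm(cfg.d_s, dtype=dt)
        self.norm_z_att = LayerNorm(cfg.d_z, dtype=dt)
        self.attention = PairBiasAttention(cfg, rng)
        out_scale = 0.0 if cfg.zero_init_residuals else None
        self.norm_s_tr = LayerNorm(cfg.d_s, dtype=dt)
        self.transition_s = Transition(cfg.d_s, cfg.transition_factor, rng, dt,
                                       out_scale=out_scale)
        self.norm_opm = LayerNorm(cfg.d_s, dtype=dt)
        self.opm = OuterProductMean(cfg, rng)
        self.norm_tm_out = LayerNorm(cfg.d_z, dtype=dt)
        self.tri_mul_out = TriangleMultiplication(cfg, rng, "outgoing")
        self.norm_tm_in = LayerNorm(cfg.d_z, dtype=dt)
        self.tri_mul_in = TriangleMultiplication(cfg, rng, "incoming")
        if cfg.variant == "full":
            self.norm_ta_start = LayerNorm(cfg.d_z, dtype=dt)
            self.tri_att_start = TriangleAttention(cfg, rng, "starting")
            self.norm_ta_end = LayerNorm(cfg.d_z, dtype=dt)
            self.tri_att_end = TriangleAttention(cfg, rng, "ending")
        self.norm_z_tr = LayerNorm(cfg.d_z, dtype=dt)
        self.transition_z = Transition(cfg.d_z, cfg.transition_factor, rng, dt,
                                       out_scale=out_scale)

    def __call__(self, s: Tensor, z: Tensor, training=False, rng=None):
        s = s + self.attention(self.norm_s_att(s), self.norm_z_att(z),
                               training=training, rng=rng)
        s = s + self.transition_s(self.norm_s_tr(s))
        z = z + self.opm(self.norm_opm(s))
        z = z + self.tri_mul_out(self.norm_tm_out(z))
        z = z + self.tri_mul_in(self.norm_tm_in(z))
        if self.cfg.variant == "full":
            z = z + self.tri_att_start(self.norm_ta_start(z))
            z = z + self.tri_att_end(self.norm_ta_end(z))
        z = z + self.transition_z(self.norm_z_tr(z))
        return s, z


def transformer_block(block: TransformerBlock, s: SequenceRepresentation,
                      z: PairRepresentation) -> tuple[SequenceRepresentation, PairRepresentation]:
    """Contract wrapper: apply one block in inference mode to typed reps."""
    if s.values.shape[0] != z.values.shape[0]:
        raise ValueError("sequence and pair representations disagree on L")
    with ag.no_grad():
        so, zo = block(Tensor(s.values[None]), Tensor(z.values[None]))
    return SequenceRepresentation(so.data[0]), PairRepresentation(zo.data[0])


# ---------------------------------------------------------------------------
# denoising structure module
# ---------------------------------------------------------------------------

def _quat_update_to_rotation(bcd: Tensor) -> Tensor:
    """(L, 3) unconstrained quaternion imaginary parts → (L, 3, 3) rotations.

    Uses the AlphaFold-style parameterization q = (1, b, c, d) / |q|, which
    is exactly orthogonal by construction and smooth near the identity.
    """
    b = bcd[:, 0]
    c = bcd[:, 1]
    d = bcd[:, 2]
    n2 = 1.0 + b * b + c * c + d * d
    s = 2.0 / n2
    one = Tensor(np.ones(b.shape, dtype=bcd.data.dtype))
    r00 = one - s * (c * c + d * d)
    r01 = s * (b * c - d)
    r02 = s * (b * d + c)
    r10 = s * (b * c + d)
    r11 = one - s * (b * b + d * d)
    r12 = s * (c * d - b)
    r20 = s * (b * d - c)
    r21 = s * (c * d + b)
    r22 = one - s * (b * b + c * c)
    rows = [ag.stack([r00, r01, r02], axis=-1),
            ag.stack([r10, r11, r12], axis=-1),
            ag.stack([r20, r21, r22], axis=-1)]
    return ag.stack(rows, axis=-2)


def _orthogonalize_straight_through(r: Tensor) -> Tensor:
    """Symmetric-orthogonalization cleanup with identity gradient.

    The incoming rotations are already orthogonal to float precision (they
    are composed quaternion rotations), so the cleanup is a sub-epsilon
    correction; gradients pass through unchanged.
    """
    cleaned = np.stack([symmetric_orthogonalize(m) for m in r.data])
    return r + Tensor(cleaned - r.data)


class InvariantPointAttention(Module):
    """Simplified invariant point attention over rigid frames."""

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        dt = cfg.np_dtype()
        self.h = cfg.ipa_heads
        self.dh = max(cfg.d_s // cfg.ipa_heads, 4)
        self.p = cfg.ipa_query_points
        d_s, d_z = cfg.d_s, cfg.d_z
        h, dh, p = self.h, self.dh, self.p
        self.q = Linear(d_s, h * dh, rng, bias=False, dtype=dt)
        self.k = Linear(d_s, h * dh, rng, bias=False, dtype=dt)
        self.v = Linear(d_s, h * dh, rng, bias=False, dtype=dt)
        self.qp = Linear(d_s, h * p * 3, rng, bias=False, dtype=dt)
        self.kp = Linear(d_s, h * p * 3, rng, bias=False, dtype=dt)
        self.vp = Linear(d_s, h * p * 3, rng, bias=False, dtype=dt)
        self.pair_bias = Linear(d_z, h, rng, bias=False, dtype=dt)
        self.head_weight = Tensor.param(np.zeros(h, dtype=dt))
        self.out = Linear(h * (dh + d_z + p * 4), d_s, rng, dtype=dt)

    def __call__(self, s: Tensor, z: Tensor, rot: Tensor, tr: Tensor):
        L = s.shape[0]
        h, dh, p = self.h, self.dh, self.p
        q = self.q(s).reshape(L, h, dh)
        k = self.k(s).reshape(L, h, dh)
        v = self.v(s).reshape(L, h, dh)
        qp = self.qp(s).reshape(L, h, p, 3)
        kp = self.kp(s).reshape(L, h, p, 3)
        vp = self.vp(s).reshape(L, h, p, 3)
        # local → global points
        tr_b = tr.reshape(L, 1, 1, 3)
        qp_g = ag.einsum("iab,ihpb->ihpa", rot, qp) + tr_b
        kp_g = ag.einsum("iab,ihpb->ihpa", rot, kp) + tr_b
        vp_g = ag.einsum("iab,ihpb->ihpa", rot, vp) + tr_b
        logits = ag.einsum("ihd,jhd->hij", q, k) * (1.0 / np.sqrt(dh))
        h_, p_ = self.h, self.p
        diff = qp_g.reshape(L, 1, h_, p_, 3) - kp_g.reshape(1, L, h_, p_, 3)
        dist2 = (diff * diff).sum(axis=-1).sum(axis=-1)    # (L, L, h)
        gamma = self.head_weight.softplus()                # (h,)
        wc = np.sqrt(2.0 / (9.0 * p))
        logits = logits - (gamma.reshape(h, 1, 1) * (0.5 * wc)) * dist2.transpose(2, 0, 1)
        logits = logits + self.pair_bias(z).transpose(2, 0, 1)
        att = ag.softmax(logits, axis=-1)                  # (h, L, L)
        o_scalar = ag.einsum("hij,jhd->ihd", att, v).reshape(L, h * dh)
        o_pair = ag.einsum("hij,ijc->ihc", att, z).reshape(L, h * z.shape[-1])
        o_pt_g = ag.einsum("hij,jhpa->ihpa", att, vp_g)
        # back to local frame of i
        o_pt = ag.einsum("iba,ihpb->ihpa", rot, o_pt_g - tr_b)
        o_norm = ((o_pt * o_pt).sum(axis=-1) + 1e-8).sqrt()  # (L, h, p)
        feats = ag.concatenate([o_scalar, o_pair,
                                o_pt.reshape(L, h * p * 3),
                                o_norm.reshape(L, h * p)], axis=-1)
        return self.out(feats)


class DenoisingStructureModule(Module):
    """Iterative frame refinement with distogram and pair-error heads."""

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        dt = cfg.np_dtype()
        self.cfg = cfg
        self.norm_s = LayerNorm(cfg.d_s, dtype=dt)
        self.norm_z = LayerNorm(cfg.d_z, dtype=dt)
        self.ipa = InvariantPointAttention(cfg, rng)
        self.norm_ipa = LayerNorm(cfg.d_s, dtype=dt)
        self.transition = Transition(cfg.d_s, 2, rng, dt)
        self.norm_tr = LayerNorm(cfg.d_s, dtype=dt)
        self.to_update = Linear(cfg.d_s, 6, rng, scale=1e-3, dtype=dt)
        self.distogram_head = Linear(cfg.d_z, DIST_CHANNELS * N_DIST_BINS, rng, dtype=dt)
        self.error_head = Linear(cfg.d_z, 1, rng, dtype=dt)

    def __call__(self, s: Tensor, z: Tensor, init: FrameSet,
                 training: bool = False, seed: int | None = None):
        """Returns (rotations Tensor (L,3,3), translations Tensor (L,3),
        distogram probs Tensor (3,L,L,40), pair-error Tensor (L,L))."""
        cfg = self.cfg
        start = init
        if training:
            start = perturb_frames(init, cfg.denoise_w, cfg.denoise_sigma,
                                   0 if seed is None else seed)
        dt = cfg.np_dtype()
        rot = Tensor(start.rotations.astype(dt))
        tr = Tensor(start.translations.astype(dt))
        s = self.norm_s(s)
        z = self.norm_z(z)
        for _ in range(cfg.ipa_iterations):
            s = s + self.ipa(s, z, rot, tr)
            s = self.norm_ipa(s)
            s = s + self.transition(s)
            s = self.norm_tr(s)
            upd = self.to_update(s)                    # (L, 6)
            r_upd = _quat_update_to_rotation(upd[:, :3])
            t_upd = upd[:, 3:]
            # compose the predicted update on the left of the current frame
            rot = ag.einsum("iab,ibc->iac", r_upd, rot)
            tr = ag.einsum("iab,ib->ia", r_upd, tr) + t_upd
            rot = _orthogonalize_straight_through(rot)
        L = z.shape[0]
        logits = self.distogram_head(z).reshape(L, L, DIST_CHANNELS, N_DIST_BINS)
        dist = ag.softmax(logits, axis=-1).transpose(2, 0, 1, 3)
        perr = self.error_head(z).reshape(L, L).softplus()
        return rot, tr, dist, perr


def drsm_forward(drsm: DenoisingStructureModule, s, z, init: FrameSet,
                 training: bool = False, seed: int | None = None
                 ) -> tuple[FrameSet, Distogram, PairErrorMap]:
    """Contract wrapper: run the DRSM on representations, return typed outputs."""
    s_t = Tensor(np.asarray(s.values if isinstance(s, SequenceRepresentation) else s))
    z_t = Tensor(np.asarray(z.values if isinstance(z, PairRepresentation) else z))
    ctx = ag.no_grad() if not training else _NullCtx()
    with ctx:
        rot, tr, dist, perr = drsm(s_t, z_t, init, training=training, seed=seed)
    frames = FrameSet(np.stack([symmetric_orthogonalize(m) for m in rot.data.astype(float)]),
                      tr.data.astype(float))
    return frames, Distogram(dist.data.astype(float)), PairErrorMap(perr.data.astype(float))


class _NullCtx:
    def __enter__(self):
        return self

    def __exit__(self, *a):
        return False


# ---------------------------------------------------------------------------
# full models
# ---------------------------------------------------------------------------

class RCLMModel(Module):
    """Composite language model: embedder + reduced blocks + two heads.

    ``forward`` takes a one-hot batch (B, L, 5) and returns 4-class sequence
    logits (B, L, 4) and 16-class ordered-pair logits (B, L, L, 16).
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        cfg.in_dim = 5
        dt = cfg.np_dtype()
        self.cfg = cfg
        self.embedder = Embedder(cfg, rng)
        for idx in range(cfg.n_blocks):
            setattr(self, f"block{idx}", TransformerBlock(cfg, rng))
        self.norm_s_out = LayerNorm(cfg.d_s, dtype=dt)
        self.norm_z_out = LayerNorm(cfg.d_z, dtype=dt)
        self.seq_head = Linear(cfg.d_s, 4, rng, dtype=dt)
        self.pair_head = Linear(cfg.d_z, 16, rng, dtype=dt)

    def blocks(self):
        return [getattr(self, f"block{i}") for i in range(self.cfg.n_blocks)]

    def forward(self, x: Tensor, training=False, rng=None):
        s, z = self.embedder(x)
        for blk in self.blocks():
            s, z = blk(s, z, training=training, rng=rng)
        seq_logits = self.seq_head(self.norm_s_out(s))
        pair_logits = self.pair_head(self.norm_z_out(z))
        return seq_logits, pair_logits

    def predict(self, symbols: str):
        """Inference on one (possibly masked, 'N') sequence → probability arrays
        (L, 4) and (L, L, 16)."""
        x = encode_sequence(symbols, 5)
        with ag.no_grad():
            seq_logits, pair_logits = self.forward(Tensor(x[None]))
            p1 = ag.softmax(seq_logits, axis=-1).data[0].astype(float)
            p2 = ag.softmax(pair_logits, axis=-1).data[0].astype(float)
        return p1, p2

    def predict_batch(self, onehot: np.ndarray):
        with ag.no_grad():
            seq_logits, pair_logits = self.forward(Tensor(onehot))
            p1 = ag.softmax(seq_logits, axis=-1).data.astype(float)
            p2 = ag.softmax(pair_logits, axis=-1).data.astype(float)
        return p1, p2


class FoldingModel(Module):
    """End-to-end folding stack: embedder + full blocks + DRSM."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        cfg.in_dim = 4
        cfg.variant = "full"
        self.cfg = cfg
        self.embedder = Embedder(cfg, rng)
        for idx in range(cfg.n_blocks):
            setattr(self, f"block{idx}", TransformerBlock(cfg, rng))
        self.drsm = DenoisingStructureModule(cfg, rng)

    def blocks(self):
        return [getattr(self, f"block{i}") for i in range(self.cfg.n_blocks)]

    def forward(self, symbols: str, init: FrameSet | None = None,
                training: bool = False, seed: int | None = None, rng=None):
        x = encode_sequence(symbols, 4)
        if init is None:
            init = FrameSet.identity(len(symbols))
        s, z = self.embedder(Tensor(x[None]))
        for blk in self.blocks():
            s, z = blk(s, z, training=training, rng=rng)
        return self.drsm(s.reshape(*s.shape[1:]), z.reshape(*z.shape[1:]), init,
                         training=training, seed=seed)

    def predict(self, symbols: str, init: FrameSet | None = None):
        with ag.no_grad():
            rot, tr, dist, perr = self.forward(symbols, init=init, training=False)
        frames = FrameSet(np.stack([symmetric_orthogonalize(m) for m in rot.data.astype(float)]),
                          tr.data.astype(float))
        return frames, Distogram(dist.data.astype(float)), PairErrorMap(perr.data.astype(float))


# ---------------------------------------------------------------------------
# checkpoints: npz archive with embedded JSON config
# ---------------------------------------------------------------------------

_MODEL_KINDS = {"rclm": RCLMModel, "folding": FoldingModel}


def save_model(model: Module, path, extra: dict | None = None) -> None:
    kind = "rclm" if isinstance(model, RCLMModel) else "folding"
    meta = {"format": 1, "kind": kind, "config": asdict(model.cfg)}
    if extra:
        meta["extra"] = extra
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_model(path) -> Module:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k[len("param/"):]: archive[k] for k in archive.files if k.startswith("param/")}
    cfg = NetworkConfig(**meta["config"])
    model = _MODEL_KINDS[meta["kind"]](cfg, np.random.default_rng(0))
    model.load_state_dict(state)
    return model
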