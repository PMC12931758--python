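"""The composite language model (CL) objective for RNA sequences.

A masked language model normally maximizes the pseudo-likelihood
``∏_{i∈M} P(X_i = x_i)`` of the masked set M, treating masked tokens as
conditionally independent.  The composite-likelihood objective adds ordered
second-order terms: the loss is

    L = −Σ_{i∈M} log P(X_i = x_i)
        −Σ_{(i,j): i≠j, i∈M or j∈M} log P(X_i = x_i, X_j = x_j)

where the joint over an *ordered* pair is a 16-class categorical
(class = 4·a + b for states X_i = a, X_j = b).  The pair sum runs over
ordered pairs with at least one masked endpoint; pairs with both positions
unmasked contribute nothing.

This module provides masking, the loss, the marginalization of the pair head
into a nucleotide-wise distribution (the "marginalized" read-out of the pair
head), the masked-recovery metric, and a desk-scale training loop over the
transformer models in :mod:`rnaforge.networks`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from ._nn import Adam
from .errors import IngestError
from .networks import (ALPHABET, MASK_INDEX, NetworkConfig, RCLMModel,
                       one_hot, save_model)

__all__ = [
    "RnaSequence",
    "MaskedBatch",
    "NucleotideDistribution",
    "PairJointDistribution",
    "TrainConfig",
    "mask_sequence",
    "composite_loss",
    "marginalize_pair",
    "train_rclm",
    "sequence_recovery",
]

PROB_FLOOR = 1e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A, C, G, U}; DNA-style T is normalized to U."""

    symbols: str
    id: str = ""

    def __post_init__(self):
        s = self.symbols.upper().replace("T", "U")
        if len(s) < 1:
            raise IngestError("empty sequence")
        bad = set(s) - set(ALPHABET)
        if bad:
            raise IngestError(f"illegal symbols in sequence: {sorted(bad)}")
        object.__setattr__(self, "symbols", s)

    def __len__(self):
        return len(self.symbols)

    @property
    def indices(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(ALPHABET)}
        return np.array([lut[c] for c in self.symbols], dtype=np.int64)


@dataclass(frozen=True)
class MaskedBatch:
    """A sequence with a non-empty masked position set (0-based indices)."""

    original: RnaSequence
    masked_positions: frozenset

    def __post_init__(self):
        m = frozenset(int(i) for i in self.masked_positions)
        if not m:
            raise ValueError("masked position set must be non-empty")
        if min(m) < 0 or max(m) >= len(self.original):
            raise ValueError("masked positions out of range")
        object.__setattr__(self, "masked_positions", m)

    @property
    def visible(self) -> str:
        """The sequence with the mask placeholder 'N' at masked positions."""
        chars = list(self.original.symbols)
        for i in self.masked_positions:
            chars[i] = "N"
        return "".join(chars)


@dataclass
class NucleotideDistribution:
    """Per-position 4-class probabilities, shape (L, 4)."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("expected an (L, 4) probability matrix")
        if (p < -1e-9).any() or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("rows must be probability vectors")
        self.probs = p

    def __len__(self):
        return self.probs.shape[0]


@dataclass
class PairJointDistribution:
    """Ordered-pair 16-class probabilities, shape (L, L, 16); class = 4a + b."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 3 or p.shape[0] != p.shape[1] or p.shape[2] != 16:
            raise ValueError("expected an (L, L, 16) probability array")
        if (p < -1e-9).any() or not np.allclose(p.sum(axis=2), 1.0, atol=1e-6):
            raise ValueError("each (i, j) slice must be a probability vector")
        self.probs = p

    def __len__(self):
        return self.probs.shape[0]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def mask_sequence(seq: RnaSequence, fraction: float = 0.15, seed: int = 0) -> MaskedBatch:
    """Mask ⌈fraction·L⌉ distinct positions, uniformly without replacement."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"mask fraction must lie in (0, 1], got {fraction}")
    L = len(seq)
    n = int(np.ceil(fraction * L))
    rng = np.random.default_rng(seed)
    positions = rng.choice(L, size=n, replace=False)
    return MaskedBatch(seq, frozenset(int(i) for i in positions))


def _ordered_pair_index(L: int, masked: np.ndarray):
    """Ordered pairs (i, j), i≠j, with i or j masked."""
    is_masked = np.zeros(L, dtype=bool)
    is_masked[masked] = True
    ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    keep = (ii != jj) & (is_masked[ii] | is_masked[jj])
    return ii[keep], jj[keep]


def composite_loss(seq_pred: NucleotideDistribution, pair_pred: PairJointDistribution,
                   batch: MaskedBatch, include_pairs: bool = True) -> float:
    """Negative log composite likelihood of the true symbols under the heads.

    Probabilities are floored at 1e-9 before the logarithm; the value is a
    sum (not a mean) over the first- and second-order terms.  With
    ``include_pairs=False`` only the first-order sum remains, which is the
    standard pseudo-likelihood masked-LM loss.
    """
    L = len(batch.original)
    if len(seq_pred) != L or len(pair_pred) != L:
        raise ValueError("prediction shapes do not match sequence length")
    x = batch.original.indices
    masked = np.fromiter(batch.masked_positions, dtype=np.int64)
    p1 = np.maximum(seq_pred.probs[masked, x[masked]], PROB_FLOOR)
    loss = -np.log(p1).sum()
    if include_pairs:
        ii, jj = _ordered_pair_index(L, masked)
        cls = 4 * x[ii] + x[jj]
        p2 = np.maximum(pair_pred.probs[ii, jj, cls], PROB_FLOOR)
        loss += -np.log(p2).sum()
    return float(loss)


def marginalize_pair(pair_pred: PairJointDistribution) -> NucleotideDistribution:
    """Collapse the 16-class pair head into a nucleotide-wise distribution.

    For position i, each (i, j) slice is summed over the partner state and
    the result averaged over all j ≠ i, then renormalized.
    """
    L = len(pair_pred)
    if L < 2:
        raise ValueError("marginalization requires at least two positions")
    joint = pair_pred.probs.reshape(L, L, 4, 4)
    mine = joint.sum(axis=3)                        # P(X_i = a) from slice (i, j)
    mask = ~np.eye(L, dtype=bool)
    marg = (mine * mask[:, :, None]).sum(axis=1) / (L - 1)
    marg /= marg.sum(axis=1, keepdims=True)
    return NucleotideDistribution(marg)


def sequence_recovery(model: RCLMModel, batch: MaskedBatch,
                      use_marginalized: bool = False) -> float:
    """Fraction of masked positions whose argmax prediction matches the truth.

    Ties break toward the lowest class index (argmax convention).  With
    ``use_marginalized=True`` the marginalized pair head is scored instead of
    the 4-class sequence head.
    """
    p1, p2 = model.predict(batch.visible)
    if use_marginalized:
        dist = marginalize_pair(PairJointDistribution(p2)).probs
    else:
        dist = p1
    masked = np.fromiter(batch.masked_positions, dtype=np.int64)
    pred = dist[masked].argmax(axis=1)
    return float((pred == batch.original.indices[masked]).mean())


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Desk-scale training settings for the composite language model."""

    steps: int = 200
    batch_size: int = 4
    mask_fraction: float = 0.15
    # BERT-style corruption of selected positions: mask symbol / random
    # nucleotide / unchanged.  All selected positions are supervised either
    # way; the random/keep fractions force the model to stay context-
    # sensitive at visible positions, which the categorical-Jacobian probe
    # (run on complete sequences) relies on.
    mask_prob: float = 0.8
    random_prob: float = 0.1
    learning_rate: float = 2.5e-3   # peak; see warmup/decay below
    # linear warmup followed by cosine decay to final_lr_fraction · peak
    warmup_steps: int = 100
    final_lr_fraction: float = 0.1
    crop_limit: int = 128           # random contiguous crop for longer sequences
    checkpoint_interval: int = 0    # 0 disables intermediate checkpoints
    checkpoint_dir: str | None = None
    log_path: str | None = None
    network: NetworkConfig = field(default_factory=NetworkConfig)


def _log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t - t.data.max(axis=axis, keepdims=True)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def _composite_loss_t(seq_logits: Tensor, pair_logits: Tensor, x: np.ndarray,
                      masked: np.ndarray):
    """Differentiable per-sequence loss terms from logits.

    Returns (seq_term_sum, pair_term_sum, n_seq_terms, n_pair_terms).  The
    training loop balances the two likelihood terms by their counts (the
    plain sum would let the ~2·L·|M| pair terms swamp the |M| first-order
    terms); the reported composite loss remains the unweighted sum.
    """
    L = x.shape[0]
    logp1 = _log_softmax(seq_logits)
    seq_term = -(logp1[masked, x[masked]]).sum()
    ii, jj = _ordered_pair_index(L, masked)
    logp2 = _log_softmax(pair_logits)
    cls = 4 * x[ii] + x[jj]
    pair_term = -(logp2[ii, jj, cls]).sum()
    return seq_term, pair_term, len(masked), len(ii)


def train_rclm(corpus, config: TrainConfig | None = None, seed: int = 0) -> RCLMModel:
    """Train a composite language model on a corpus of :class:`RnaSequence`.

    Deterministic given ``seed`` on a single worker.  Each step draws a batch
    with replacement, masks ``mask_fraction`` of positions per sequence
    (mask symbol in the one-hot input), and takes one Adam step on the
    per-token-normalized composite loss.  Returns the trained model; training
    curves go to ``config.log_path`` (TSV) and checkpoints to
    ``config.checkpoint_dir`` when configured.
    """
    config = config or TrainConfig()
    corpus = [s if isinstance(s, RnaSequence) else RnaSequence(s) for s in corpus]
    if not corpus:
        raise IngestError("empty training corpus")
    rng = np.random.default_rng(seed)
    model = RCLMModel(config.network, rng)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    log_rows = []

    def lr_at(step: int) -> float:
        peak = config.learning_rate
        if config.warmup_steps > 0 and step < config.warmup_steps:
            return peak * (step + 1) / config.warmup_steps
        if config.steps <= config.warmup_steps:
            return peak
        t = (step - config.warmup_steps) / max(config.steps - config.warmup_steps, 1)
        floor_lr = config.final_lr_fraction * peak
        return floor_lr + 0.5 * (peak - floor_lr) * (1 + np.cos(np.pi * t))

    for step in range(config.steps):
        opt.lr = lr_at(step)
        idx = rng.integers(0, len(corpus), size=config.batch_size)
        seq_total = pair_total = None
        n_seq = n_pair = 0
        # group batch members by (cropped) length so same-length members stack
        members = []
        for k in idx:
            x = corpus[k].indices
            if x.shape[0] > config.crop_limit:
                start = rng.integers(0, x.shape[0] - config.crop_limit + 1)
                x = x[start:start + config.crop_limit]
            L = x.shape[0]
            n_mask = int(np.ceil(config.mask_fraction * L))
            masked = rng.choice(L, size=n_mask, replace=False)
            members.append((x, masked))
        by_len = {}
        for x, masked in members:
            by_len.setdefault(x.shape[0], []).append((x, masked))
        for L, group in by_len.items():
            xs = np.stack([x for x, _ in group])
            vis = xs.copy()
            for b, (_, masked) in enumerate(group):
                u = rng.random(len(masked))
                for pos, draw in zip(masked, u):
                    if draw < config.mask_prob:
                        vis[b, pos] = MASK_INDEX
                    elif draw < config.mask_prob + config.random_prob:
                        vis[b, pos] = rng.integers(0, 4)
                    # else: keep the original symbol (still supervised)
            onehot = one_hot(vis, 5)
            seq_logits, pair_logits = model.forward(Tensor(onehot), training=True, rng=rng)
            for b, (x, masked) in enumerate(group):
                s_term, p_term, ns, npair = _composite_loss_t(
                    seq_logits[b], pair_logits[b], x, masked)
                seq_total = s_term if seq_total is None else seq_total + s_term
                pair_total = p_term if pair_total is None else pair_total + p_term
                n_seq += ns
                n_pair += npair
        loss = seq_total * (1.0 / n_seq) + pair_total * (1.0 / max(n_pair, 1))
        opt.zero_grad()
        loss.backward()
        opt.step()
        log_rows.append((step, float(loss.data)))
        if config.checkpoint_interval and config.checkpoint_dir \
                and (step + 1) % config.checkpoint_interval == 0:
            path = Path(config.checkpoint_dir) / f"rclm_step{step + 1:06d}.npz"
            path.parent.mkdir(parents=True, exist_ok=True)
            save_model(model, path, extra={"step": step + 1, "seed": seed})
    if config.log_path:
        Path(config.log_path).parent.mkdir(parents=True, exist_ok=True)
        with open(config.log_path, "w") as fh:
            fh.write("step\tloss_per_token\n")
            for step, value in log_rows:
                fh.write(f"{step}\t{value:.6f}\n")
    model.train_log = log_rows
    return model
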