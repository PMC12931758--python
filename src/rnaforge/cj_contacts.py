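"""Unsupervised contact extraction via the categorical Jacobian.

Any model that maps an RNA sequence to a per-position nucleotide
distribution f(X) (shape L × 4) exposes its learned couplings through
finite differences over single-position mutations:

    J[i, a, j, b] = f(X with x_i → a)[j, b] − f(X)[j, b]

The coupling tensor is collapsed to an L × L map by the Euclidean norm over
the two nucleotide axes, M_ij = sqrt(Σ_ab J²), and the Average Product
Correction removes background coupling:

    C_ij = M_ij − (Σ_i' M_i'j)(Σ_j' M_ij') / (Σ_i'j' M_i'j')

Contacts are ranked from the symmetrized, separation-filtered corrected map;
top-N precision is evaluated against true contacts defined either by a
coordinate threshold on glycosidic-N distances (default 12 Å) or by an
explicit pair set.

Both heads of the composite language model run through the same pipeline:
the 4-class sequence head directly, and the 16-class pair head after
marginalization into a nucleotide-wise distribution (the marginalized
read-out).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import CoarseStructure

__all__ = [
    "CouplingTensor",
    "ContactMap",
    "categorical_jacobian",
    "collapse_coupling",
    "apc",
    "top_n_precision",
    "ranked_contacts",
    "true_contact_set",
    "rclm_model_fn",
    "rclm_marginal_model_fn",
    "jacobian_from_model",
]

DEFAULT_MIN_SEPARATION = 4
DEFAULT_CONTACT_THRESHOLD = 12.0  # Å on N–N distance; 16 and 20 Å are common too


@dataclass
class CouplingTensor:
    """Finite-difference couplings J, shape (L, 4, L, 4)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 4 or v.shape[1] != 4 or v.shape[3] != 4 or v.shape[0] != v.shape[2]:
            raise ValueError("coupling tensor must have shape (L, 4, L, 4)")
        if not np.isfinite(v).all():
            raise ValueError("coupling tensor must be finite")
        self.values = v

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class ContactMap:
    """An L × L contact score matrix with bookkeeping flags in ``meta``."""

    values: np.ndarray
    meta: dict = field(default_factory=lambda: {
        "corrected": False, "symmetrized": False,
        "min_separation": DEFAULT_MIN_SEPARATION})

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or not np.isfinite(v).all():
            raise ValueError("contact map must be a finite square matrix")
        if self.meta.get("symmetrized") and not np.allclose(v, v.T):
            raise ValueError("map flagged symmetrized but is not symmetric")
        self.values = v

    @property
    def length(self) -> int:
        return self.values.shape[0]


def _sequence_of(seq) -> str:
    return seq if isinstance(seq, str) else seq.symbols


def _check_distribution(p, L: int) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (L, 4):
        raise ValueError(f"model function must return an (L, 4) matrix, got {p.shape}")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-3):
        raise ValueError("model function returned non-normalized rows")
    return p


def categorical_jacobian(model_fn, seq) -> CouplingTensor:
    """Finite-difference coupling tensor of ``model_fn`` around ``seq``.

    ``model_fn`` maps a sequence string to an (L, 4) probability matrix.  The
    base sequence is evaluated once and reused for mutations to self, so the
    4L + 1 required evaluations reduce to 3L + 1 model calls; slices for the
    identity mutation are exactly zero.
    """
    from .networks import ALPHABET

    symbols = _sequence_of(seq)
    L = len(symbols)
    base = _check_distribution(model_fn(symbols), L)
    J = np.zeros((L, 4, L, 4))
    for i in range(L):
        for a, nt in enumerate(ALPHABET):
            if nt == symbols[i]:
                continue  # identity mutation: f(X) − f(X) = 0
            mutant = symbols[:i] + nt + symbols[i + 1:]
            J[i, a] = _check_distribution(model_fn(mutant), L) - base
    return CouplingTensor(J)


def collapse_coupling(j: CouplingTensor) -> ContactMap:
    """M_ij = sqrt(Σ_a Σ_b J[i,a,j,b]²)."""
    m = np.sqrt(np.einsum("iajb,iajb->ij", j.values, j.values))
    return ContactMap(m, {"corrected": False, "symmetrized": False,
                          "min_separation": DEFAULT_MIN_SEPARATION})


def apc(m: ContactMap) -> ContactMap:
    """Average Product Correction: C_ij = M_ij − row_i · col_j / total."""
    if m.meta.get("corrected"):
        raise ValueError("map is already APC-corrected")
    v = m.values
    total = v.sum()
    if total == 0.0:
        warnings.warn("contact map sums to zero; APC left it unchanged")
        return ContactMap(v.copy(), dict(m.meta))
    corrected = v - np.outer(v.sum(axis=1), v.sum(axis=0)) / total
    meta = dict(m.meta)
    meta["corrected"] = True
    return ContactMap(corrected, meta)


def _eligible_ranked_pairs(c: ContactMap, min_separation: int | None = None):
    """(i, j, score) for i < j with j − i ≥ min_separation, sorted by score
    descending, ties broken by (i, j) ascending; scores from the symmetrized
    map (C + Cᵀ)/2."""
    sep = c.meta.get("min_separation", DEFAULT_MIN_SEPARATION) \
        if min_separation is None else min_separation
    v = (c.values + c.values.T) / 2.0
    L = v.shape[0]
    ii, jj = np.triu_indices(L, k=sep)
    order = np.lexsort((jj, ii, -v[ii, jj]))
    return ii[order], jj[order], v[ii, jj][order]


def ranked_contacts(c: ContactMap, min_separation: int | None = None):
    """Ranked eligible contacts as (i, j, score) arrays (0-based indices)."""
    return _eligible_ranked_pairs(c, min_separation)


def true_contact_set(truth, contact_threshold: float = DEFAULT_CONTACT_THRESHOLD) -> set:
    """True contacts as a set of (i, j), i < j.

    ``truth`` is either a CoarseStructure (contacts = N–N distance below the
    threshold) or an iterable of index pairs.
    """
    if isinstance(truth, CoarseStructure):
        n = truth.n_atoms
        d = np.linalg.norm(n[:, None, :] - n[None, :, :], axis=-1)
        ii, jj = np.where(d < contact_threshold)
        return {(int(a), int(b)) for a, b in zip(ii, jj) if a < b}
    pairs = getattr(truth, "pairs", truth)
    return {(min(a, b), max(a, b)) for a, b in pairs}


def top_n_precision(c: ContactMap, truth, n: int,
                    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
                    min_separation: int | None = None) -> float:
    """Fraction of the top-n ranked eligible pairs that are true contacts."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ii, jj, _ = _eligible_ranked_pairs(c, min_separation)
    if len(ii) < n:
        warnings.warn(f"only {len(ii)} eligible pairs for top-{n}; using all")
        n = len(ii)
    true_set = true_contact_set(truth, contact_threshold)
    hits = sum((int(a), int(b)) in true_set for a, b in zip(ii[:n], jj[:n]))
    return hits / n


# ---------------------------------------------------------------------------
# adapters for the composite language model
# ---------------------------------------------------------------------------

def rclm_model_fn(model):
    """Sequence-head adapter: mutant forward passes are mask-free."""
    def fn(symbols: str):
        p1, _ = model.predict(symbols)
        return p1
    return fn


def rclm_marginal_model_fn(model):
    """Marginalized pair-head adapter (the marginalized read-out path)."""
    from .rclm import PairJointDistribution, marginalize_pair

    def fn(symbols: str):
        _, p2 = model.predict(symbols)
        return marginalize_pair(PairJointDistribution(p2)).probs
    return fn


def jacobian_from_model(model, seq, head: str = "sequence",
                        batch_size: int = 16) -> CouplingTensor:
    """Coupling tensor of a language model, batching mutant forward passes.

    Equivalent to ``categorical_jacobian`` with the corresponding adapter but
    evaluates mutants in batches for speed.  ``head`` selects the 4-class
    sequence head or the marginalized pair head ("marginal").
    """
    from .networks import ALPHABET, encode_sequence
    from .rclm import PairJointDistribution, marginalize_pair

    symbols = _sequence_of(seq)
    L = len(symbols)

    def distributions(batch_symbols):
        onehot = np.stack([encode_sequence(s, 5) for s in batch_symbols])
        p1, p2 = model.predict_batch(onehot)
        if head == "sequence":
            return [p1[b] for b in range(len(batch_symbols))]
        if head == "marginal":
            return [marginalize_pair(PairJointDistribution(p2[b])).probs
                    for b in range(len(batch_symbols))]
        raise ValueError(f"unknown head {head!r}")

    base = distributions([symbols])[0]
    mutants, where = [], []
    for i in range(L):
        for a, nt in enumerate(ALPHABET):
            if nt == symbols[i]:
                continue
            mutants.append(symbols[:i] + nt + symbols[i + 1:])
            where.append((i, a))
    J = np.zeros((L, 4, L, 4))
    for start in range(0, len(mutants), batch_size):
        chunk = mutants[start:start + batch_size]
        for (i, a), dist in zip(where[start:start + batch_size], distributions(chunk)):
            J[i, a] = dist - base
    return CouplingTensor(J)
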