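"""Structure assessment metrics.

* **kabsch_rmsd** — RMSD after optimal rigid superposition (no reflection),
  via quaternion-free least squares on centered point sets.
* **tm_score** — length-normalized template-modeling score on P atoms,
  in (0, 1]; the superposition is searched over contiguous fragment seeds
  with iterative distance-threshold refinement.  The RNA normalization
  d0 = 0.6·sqrt(L − 0.5) − 2.5 (clamped below at 0.5 Å) is used.  The
  conventional thresholds 0.45 (same fold) and 0.21 (random-pair baseline)
  are exposed as constants for report labeling only.
* **detect_base_pairs** — geometric pair detector on the coarse three-atom
  representation: greedy one-partner-per-nucleotide matching of pairs with
  sequence separation ≥ 3 whose N–N and C4'–C4' distances both fall inside
  calibrated windows.
* **inf_score / deformation_index** — interaction network fidelity
  (geometric mean of base-pair precision and recall) and DI = RMSD / INF_all.

Indices are 0-based in memory; the annotation/report I/O layer converts to
the 1-based convention exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import CoarseStructure

__all__ = [
    "BasePairSet",
    "PairDetectorConfig",
    "kabsch_rmsd",
    "superpose",
    "tm_score",
    "tm_d0",
    "detect_base_pairs",
    "inf_score",
    "deformation_index",
    "TM_FOLD_THRESHOLD",
    "TM_RANDOM_THRESHOLD",
]

TM_FOLD_THRESHOLD = 0.45    # same-fold label
TM_RANDOM_THRESHOLD = 0.21  # expected score of two random structures

CATEGORIES = ("wc", "nwc", "stack", "any")


@dataclass(frozen=True)
class BasePairSet:
    """A set of unordered nucleotide index pairs with an interaction category."""

    pairs: frozenset
    category: str = "any"
    length: int | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")
        norm = frozenset((min(i, j), max(i, j)) for i, j in self.pairs)
        for i, j in norm:
            if i == j or i < 0:
                raise ValueError(f"invalid pair ({i}, {j})")
            if self.length is not None and j >= self.length:
                raise ValueError(f"pair ({i}, {j}) outside sequence of length {self.length}")
        object.__setattr__(self, "pairs", norm)

    def __len__(self):
        return len(self.pairs)


@dataclass(frozen=True)
class PairDetectorConfig:
    """Distance windows of the geometric detector, calibrated to the toolkit's
    idealized pair geometry (N–N 9.0 Å, C4'–C4' ≈ 15.8 Å across a pair)."""

    nn_window: tuple = (7.5, 10.0)
    c4_window: tuple = (14.5, 16.6)
    min_separation: int = 3


DEFAULT_DETECTOR = PairDetectorConfig()


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation 3×3, translation 3, transformed mobile).  Proper
    rotations only.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must share shape (N, 3)")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    if mobile.shape[0] == 1:
        rot = np.eye(3)
    else:
        rot = Rotation.align_vectors(target - tc, mobile - mc)[0].as_matrix()
    shift = tc - rot @ mc
    return rot, shift, mobile @ rot.T + shift


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD (Å) after optimal rigid superposition of ``a`` onto ``b``."""
    _, _, moved = superpose(a, b)
    return float(np.sqrt(((moved - np.asarray(b, dtype=float)) ** 2).sum(axis=1).mean()))


def tm_d0(L: int, floor: float = 0.5) -> float:
    """RNA d0 normalization, clamped below at ``floor`` Å."""
    return max(floor, 0.6 * np.sqrt(L - 0.5) - 2.5)


def _tm_from_superposition(model_p, ref_p, rot, shift, d0):
    moved = model_p @ rot.T + shift
    d = np.linalg.norm(moved - ref_p, axis=1)
    return float((1.0 / (1.0 + (d / d0) ** 2)).mean()), d


def tm_score(model: CoarseStructure, ref: CoarseStructure) -> float:
    """Template-modeling score of ``model`` against ``ref`` on P atoms.

    Equal lengths are required (sequence-independent, no alignment step);
    the score is normalized by the reference length.  Fragment seeds of
    lengths L, L/2 and L/4 (minimum 4) slide along the chain; each seed
    superposition is refined by repeatedly re-superposing on residues within
    a distance threshold.  Returns the maximum over all searched
    superpositions, in (0, 1].
    """
    if len(model) != len(ref):
        raise ValueError("tm_score requires equal-length structures")
    L = len(ref)
    if L < 3:
        raise ValueError("tm_score requires at least 3 nucleotides")
    mp, rp = model.p_atoms, ref.p_atoms
    d0 = tm_d0(L)
    refine_cut = max(d0, 4.5)
    best = 0.0
    frag_lengths = sorted({L, max(4, L // 2), max(4, L // 4)}, reverse=True)
    for fl in frag_lengths:
        if fl > L:
            continue
        step = max(1, fl // 2)
        for start in range(0, L - fl + 1, step):
            window = slice(start, start + fl)
            rot, shift, _ = superpose(mp[window], rp[window])
            score, d = _tm_from_superposition(mp, rp, rot, shift, d0)
            best = max(best, score)
            prev = None
            for _ in range(20):
                sel = d < refine_cut
                if sel.sum() < 4:
                    break
                if prev is not None and np.array_equal(sel, prev):
                    break
                prev = sel
                rot, shift, _ = superpose(mp[sel], rp[sel])
                score, d = _tm_from_superposition(mp, rp, rot, shift, d0)
                best = max(best, score)
    return best


def detect_base_pairs(s: CoarseStructure,
                      config: PairDetectorConfig = DEFAULT_DETECTOR) -> BasePairSet:
    """Greedy geometric base-pair detection on the coarse representation.

    Candidate pairs need |i − j| ≥ min_separation with the N–N distance in
    ``nn_window`` and the C4'–C4' distance in ``c4_window``; candidates are
    matched greedily by ascending N–N distance with one partner per
    nucleotide.  Deterministic; symmetric under relabeling.
    """
    n = s.n_atoms
    c4 = s.c4_atoms
    dn = np.linalg.norm(n[:, None, :] - n[None, :, :], axis=-1)
    dc = np.linalg.norm(c4[:, None, :] - c4[None, :, :], axis=-1)
    L = len(s)
    ii, jj = np.triu_indices(L, k=config.min_separation)
    ok = (dn[ii, jj] >= config.nn_window[0]) & (dn[ii, jj] <= config.nn_window[1]) \
        & (dc[ii, jj] >= config.c4_window[0]) & (dc[ii, jj] <= config.c4_window[1])
    cand = sorted(zip(dn[ii[ok], jj[ok]], ii[ok], jj[ok]))
    taken = np.zeros(L, dtype=bool)
    pairs = set()
    for _, i, j in cand:
        if not taken[i] and not taken[j]:
            taken[i] = taken[j] = True
            pairs.add((int(i), int(j)))
    return BasePairSet(frozenset(pairs), "any", length=L)


def inf_score(pred: BasePairSet, ref: BasePairSet) -> float:
    """Interaction network fidelity: sqrt(precision × recall)."""
    if pred.category != ref.category:
        raise ValueError(f"category mismatch: {pred.category} vs {ref.category}")
    if len(ref) == 0:
        raise ValueError("INF is undefined for an empty reference pair set")
    if len(pred) == 0:
        return 0.0
    tp = len(pred.pairs & ref.pairs)
    precision = tp / len(pred)
    recall = tp / len(ref)
    return float(np.sqrt(precision * recall))


def deformation_index(rmsd: float, inf_all: float) -> float:
    """DI = RMSD / INF_all; undefined (raises) when INF_all is 0."""
    if rmsd < 0:
        raise ValueError("RMSD must be non-negative")
    if inf_all <= 0:
        raise ValueError("deformation index is undefined for INF_all <= 0")
    return float(rmsd / inf_all)
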