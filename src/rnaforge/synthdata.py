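"""Synthetic data: covariation-bearing RNA families, toy coarse-grained 3D
structures, and noisy decoy pools with matched distograms.

The family model is an explicit pair-complementarity model rather than a
fitted Potts model: a nested secondary-structure spec plants column pairs;
paired columns draw a complementary nucleotide combination (AU/UA/GC/CG/
GU/UG, uniform) with probability ``complement_prob`` and independent
background letters otherwise; every symbol is then hit by uniform mutation
noise at ``mutation_rate``.  This gives controllable covariation strength
and analytic expectations for the recovery tests.

Toy 3D structures embed a secondary-structure spec as a planar
ladder-and-arc layout (the classical secondary-structure drawing): stems are
straight ladders with 6 Å backbone rise and 19 Å strand separation, loops
are circular arcs; the C4' and glycosidic-N atoms sit at fixed offsets
toward the pairing partner (or the loop center), which puts every planted
pair — and only planted pairs — inside the geometric pair detector's
distance windows.

Decoy pools perturb the reference's frames with the toolkit's denoising
perturbation at a list of translation noise scales (round-robin) and attach
synthetic distograms that put ``sharpness`` of the probability mass on the
reference's true distance bin (remainder uniform), with uniform pair-error
maps.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .csor import Decoy, DecoyPool
from .fold_losses import DEFAULT_BINNING, DistanceBinning, bin_distances
from .geometry import (CoarseStructure, frames_from_atoms, perturb_frames)
from .networks import ALPHABET, Distogram, N_DIST_BINS, PairErrorMap
from .rclm import RnaSequence

__all__ = [
    "FamilySpec",
    "sample_structure_spec",
    "sample_family",
    "build_toy_structure",
    "make_decoy_pool",
    "MIN_LOOP",
]

MIN_LOOP = 3                      # minimum hairpin loop length
BACKBONE_RISE = 6.0               # Å between consecutive backbone anchors
STRAND_SEPARATION = 19.0          # Å between paired backbone anchors
C4_INWARD = 1.6                   # C4' offset toward the partner
C4_LIFT = 1.3                     # C4' out-of-plane offset
N_INWARD = 5.0                    # glycosidic N offset toward the partner (paired)
N_LOOP_INWARD = 2.5               # shorter N offset for unpaired residues

COMPLEMENTARY = [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]  # AU UA CG GC GU UG


@dataclass(frozen=True)
class FamilySpec:
    """A sequence family: length, planted non-crossing pairs, signal levels."""

    length: int
    pair_list: tuple                  # 0-based (i, j) tuples, i < j
    complement_prob: float = 0.9
    mutation_rate: float = 0.02
    background: tuple = (0.30, 0.20, 0.22, 0.28)  # A/U-rich, as in real ncRNA

    def __post_init__(self):
        pairs = tuple(sorted((min(i, j), max(i, j)) for i, j in self.pair_list))
        seen = set()
        for i, j in pairs:
            if not (0 <= i < j < self.length):
                raise ValueError(f"pair ({i}, {j}) out of range for length {self.length}")
            if j - i < MIN_LOOP + 1:
                raise ValueError(f"pair ({i}, {j}) violates the minimum loop of {MIN_LOOP}")
            if i in seen or j in seen:
                raise ValueError("pair list must use disjoint positions")
            seen.update((i, j))
        for (i1, j1) in pairs:
            for (i2, j2) in pairs:
                if i1 < i2 < j1 < j2:
                    raise ValueError(f"crossing pairs ({i1},{j1}) and ({i2},{j2})")
        if not 0.0 <= self.complement_prob <= 1.0:
            raise ValueError("complement_prob must lie in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg < 0).any() or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be a 4-class probability vector")
        object.__setattr__(self, "pair_list", pairs)
        object.__setattr__(self, "background", tuple(bg))

    @property
    def paired_columns(self) -> set:
        return {i for p in self.pair_list for i in p}


# ---------------------------------------------------------------------------
# uniform sampling of nested pair sets
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _nested_counts(length: int, max_pairs: int, min_span: int):
    """ways[l][k]: number of non-crossing k-pair configurations on l positions
    with every pair spanning at least ``min_span`` (exact big-int DP)."""
    ways = [[0] * (max_pairs + 1) for _ in range(length + 1)]
    for l in range(length + 1):
        ways[l][0] = 1
    for l in range(1, length + 1):
        for k in range(1, max_pairs + 1):
            total = ways[l - 1][k]  # first position unpaired
            for m in range(min_span, l):  # first position paired with offset m
                inner, outer = m - 1, l - m - 1
                for k1 in range(0, k):
                    if k1 <= inner // 2 and (k - 1 - k1) >= 0:
                        total += ways[inner][k1] * ways[outer][k - 1 - k1]
            ways[l][k] = total
    return ways


def sample_structure_spec(L: int, n_pairs: int, seed: int,
                          complement_prob: float = 0.9,
                          mutation_rate: float = 0.02) -> FamilySpec:
    """Uniformly sample a valid nested pair configuration.

    Exact uniformity over all non-crossing sets of ``n_pairs`` pairs with
    minimum loop :data:`MIN_LOOP`, via big-integer interval counting.
    """
    min_span = MIN_LOOP + 1
    if n_pairs < 0 or n_pairs > max((L - MIN_LOOP) // 2, 0):
        raise ValueError(f"{n_pairs} pairs are infeasible for length {L}")
    ways = _nested_counts(L, n_pairs, min_span)
    if ways[L][n_pairs] == 0:
        raise ValueError(f"no valid configuration with {n_pairs} pairs at length {L}")
    rng = random.Random(seed)
    pairs = []

    def sample(offset: int, l: int, k: int):
        while l > 0 and k > 0:
            draw = rng.randrange(ways[l][k])
            if draw < ways[l - 1][k]:
                offset += 1
                l -= 1
                continue
            draw -= ways[l - 1][k]
            for m in range(min_span, l):
                inner, outer = m - 1, l - m - 1
                for k1 in range(0, k):
                    if k1 > inner // 2:
                        continue
                    block = ways[inner][k1] * ways[outer][k - 1 - k1]
                    if draw < block:
                        # block chosen ∝ its size; the two sub-segments are
                        # then themselves uniform, so overall uniformity holds
                        pairs.append((offset, offset + m))
                        sample(offset + 1, inner, k1)
                        sample(offset + m + 1, outer, k - 1 - k1)
                        return
                    draw -= block
            raise AssertionError("count bookkeeping error")

    sample(0, L, n_pairs)
    return FamilySpec(L, tuple(pairs), complement_prob, mutation_rate)


def sample_family(spec: FamilySpec, n: int, seed: int):
    """Draw ``n`` sequences from the family model as :class:`RnaSequence`."""
    if n < 1:
        raise ValueError("need at least one sequence")
    rng = np.random.default_rng(seed)
    L = spec.length
    bg = np.asarray(spec.background)
    paired = spec.paired_columns
    unpaired = sorted(set(range(L)) - paired)
    out = []
    for s in range(n):
        x = np.zeros(L, dtype=np.int64)
        if unpaired:
            x[unpaired] = rng.choice(4, size=len(unpaired), p=bg)
        for i, j in spec.pair_list:
            if rng.random() < spec.complement_prob:
                a, b = COMPLEMENTARY[rng.integers(len(COMPLEMENTARY))]
                x[i], x[j] = a, b
            else:
                x[i] = rng.choice(4, p=bg)
                x[j] = rng.choice(4, p=bg)
        if spec.mutation_rate > 0:
            hit = rng.random(L) < spec.mutation_rate
            x[hit] = rng.integers(0, 4, size=hit.sum())
        out.append(RnaSequence("".join(ALPHABET[c] for c in x), id=f"fam{s:05d}"))
    return out


# ---------------------------------------------------------------------------
# toy 3D structures
# ---------------------------------------------------------------------------

def _partner_array(spec: FamilySpec) -> np.ndarray:
    partner = np.full(spec.length, -1, dtype=np.int64)
    for i, j in spec.pair_list:
        partner[i], partner[j] = j, i
    return partner


def _arc_chain(p_start: np.ndarray, p_end: np.ndarray, normal: np.ndarray,
               chords):
    """Anchor points between ``p_start`` and ``p_end`` separated by the given
    straight-line (chord) distances, on a circular arc bulging toward
    ``normal``.

    Solves for the circle radius r such that the chain of chords c_1..c_M
    (including the closing chords to the two fixed endpoints) spans exactly
    the endpoint separation: 2 r sin(Σ_t asin(c_t / 2r)) = |p_end − p_start|.
    Falls back to a straight segment when the chords fit the chord distance.
    Returns the M−1 interior anchor points and their inward unit normals.
    """
    chords = np.asarray(chords, dtype=float)
    chord_v = p_end - p_start
    c = np.linalg.norm(chord_v)
    inner_cum = np.cumsum(chords)[:-1]
    if chords.sum() <= c * 1.001 or c < 1e-9:
        ts = inner_cum / max(chords.sum(), 1e-9)
        pts = p_start[None, :] + ts[:, None] * chord_v[None, :]
        inward = -normal / max(np.linalg.norm(normal), 1e-9)
        return pts, np.repeat(inward[None, :], len(inner_cum), axis=0)

    def span(r):
        return 2.0 * r * np.sin(np.arcsin(np.clip(chords / (2.0 * r), -1.0, 1.0)).sum())

    # bracket: span(r) → Σc_t > c as r → ∞; shrink r until span < c
    r_hi = max(chords.sum(), c)
    r_lo = chords.max() / 2.0 + 1e-9
    r = r_hi
    while span(r) > c and r > r_lo * 1.0001:
        r_next = max(r * 0.7, r_lo)
        if span(r_next) < c:
            from scipy.optimize import brentq
            r = brentq(lambda rr: span(rr) - c, r_next, r)
            break
        r = r_next
    theta = 2.0 * np.arcsin(np.clip(chords / (2.0 * r), -1.0, 1.0)).sum()
    u = chord_v / c
    nrm = normal - np.dot(normal, u) * u
    nrm = nrm / max(np.linalg.norm(nrm), 1e-9)
    mid = (p_start + p_end) / 2.0
    # center on the far side of the bulge (arc midpoint lands at mid + nrm (r − h))
    center = mid - nrm * (r * np.cos(theta / 2.0))
    v0 = p_start - center
    ang0 = np.arctan2(np.dot(v0, nrm), np.dot(v0, u))
    steps = 2.0 * np.arcsin(np.clip(chords / (2.0 * r), -1.0, 1.0))
    # travel direction: after the full sweep we must land on p_end
    v1 = p_end - center
    ang1 = np.arctan2(np.dot(v1, nrm), np.dot(v1, u))

    def wrap(a):
        return (a + np.pi) % (2.0 * np.pi) - np.pi

    sign = 1.0 if abs(wrap(ang0 + theta - ang1)) <= abs(wrap(ang0 - theta - ang1)) else -1.0
    angs = ang0 + sign * np.cumsum(steps)[:-1]
    pts = center[None, :] + r * (np.cos(angs)[:, None] * u[None, :]
                                 + np.sin(angs)[:, None] * nrm[None, :])
    inward = center[None, :] - pts
    inward /= np.linalg.norm(inward, axis=1, keepdims=True)
    return pts, inward


def build_toy_structure(spec: FamilySpec, sequence: str | None = None) -> CoarseStructure:
    """Deterministic planar embedding of a nested secondary structure.

    Paired nucleotides' N–N distances land inside the geometric detector's
    window and adjacent P–P distances stay within [4, 8] Å by construction.
    """
    L = spec.length
    partner = _partner_array(spec)
    pos = np.zeros((L, 3))       # backbone (P) anchors
    inward = np.zeros((L, 3))    # unit vector toward partner / loop center

    def helix_length(i: int) -> int:
        j = partner[i]
        h = 1
        while i + h < j - h and partner[i + h] == j - h:
            h += 1
        return h

    def layout_segment(lo: int, hi: int, p_start, p_end, normal):
        """Place residues lo..hi (inclusive) along an arc between two anchor
        points; child helices branch outward along the local arc normal."""
        items = []   # ("res", i) or ("helix", i, j)
        i = lo
        while i <= hi:
            if partner[i] > i and partner[i] <= hi:
                items.append(("helix", i, partner[i]))
                i = partner[i] + 1
            else:
                items.append(("res", i))
                i += 1
        # chord chain: backbone steps of 6 Å; a child helix occupies a 19 Å chord
        chords = []
        for item in items:
            chords.append(BACKBONE_RISE)
            if item[0] == "helix":
                chords.append(STRAND_SEPARATION)
        chords.append(BACKBONE_RISE)
        pts, inw = _arc_chain(np.asarray(p_start, float), np.asarray(p_end, float),
                              np.asarray(normal, float), chords)
        a = 0
        for item in items:
            if item[0] == "res":
                idx = item[1]
                pos[idx] = pts[a]
                inward[idx] = inw[a]
                a += 1
            else:
                _, i0, j0 = item
                base_left, base_right = pts[a], pts[a + 1]
                out_dir = -(inw[a] + inw[a + 1])
                out_dir = out_dir / max(np.linalg.norm(out_dir), 1e-9)
                layout_helix(i0, j0, base_left, base_right, out_dir)
                a += 2

    def layout_helix(i0: int, j0: int, base_left, base_right, axis):
        h = helix_length(i0)
        w = base_right - base_left
        w = w / np.linalg.norm(w)
        for t in range(h):
            left = base_left + t * BACKBONE_RISE * axis
            right = base_right + t * BACKBONE_RISE * axis
            pos[i0 + t] = left
            pos[j0 - t] = right
            inward[i0 + t] = w
            inward[j0 - t] = -w
        top_left = base_left + (h - 1) * BACKBONE_RISE * axis
        top_right = base_right + (h - 1) * BACKBONE_RISE * axis
        if i0 + h <= j0 - h:
            # the innermost pair's residues are the fixed endpoints of the loop arc
            layout_segment(i0 + h, j0 - h, top_left, top_right, axis)

    # exterior: straight line along +x, helices extending +y
    items = []
    i = 0
    while i < L:
        if partner[i] > i:
            items.append(("helix", i, partner[i]))
            i = partner[i] + 1
        else:
            items.append(("res", i))
            i += 1
    x = 0.0
    for item in items:
        if item[0] == "res":
            idx = item[1]
            pos[idx] = (x, 0.0, 0.0)
            inward[idx] = (0.0, -1.0, 0.0)
            x += BACKBONE_RISE
        else:
            _, i0, j0 = item
            layout_helix(i0, j0, np.array([x, 0.0, 0.0]),
                         np.array([x + STRAND_SEPARATION, 0.0, 0.0]),
                         np.array([0.0, 1.0, 0.0]))
            x += STRAND_SEPARATION + BACKBONE_RISE

    coords = np.zeros((L, 3, 3))
    lift = np.array([0.0, 0.0, C4_LIFT])
    n_extent = np.where(partner >= 0, N_INWARD, N_LOOP_INWARD)
    coords[:, 0, :] = pos
    coords[:, 1, :] = pos + C4_INWARD * inward + lift
    coords[:, 2, :] = pos + n_extent[:, None] * inward
    return CoarseStructure(coords, sequence)


# ---------------------------------------------------------------------------
# decoy pools
# ---------------------------------------------------------------------------

def make_decoy_pool(ref: CoarseStructure, n: int, noise_scales=(0.5, 1.0, 2.0),
                    sharpness: float = 0.9, seed: int = 0,
                    binning: DistanceBinning = DEFAULT_BINNING) -> DecoyPool:
    """Perturbed decoys around a reference with matched synthetic distograms.

    Decoy k gets translation noise ``noise_scales[k % len(noise_scales)]``
    (Å) and a proportional rotational noise weight w = min(0.5, 0.05·σ); its
    distogram puts ``sharpness`` of the mass on the reference's true bin and
    spreads the remainder uniformly.  Pair-error maps are uniform.
    """
    if n < 1:
        raise ValueError("need at least one decoy")
    if not 0.0 <= sharpness <= 1.0:
        raise ValueError("sharpness must lie in [0, 1]")
    frames = frames_from_atoms(ref)
    L = len(ref)
    d = np.linalg.norm(ref.coords[:, None, :, :] - ref.coords[None, :, :, :],
                       axis=-1).transpose(2, 0, 1)
    bins = bin_distances(d, binning)                        # (3, L, L)
    probs = np.full((3, L, L, N_DIST_BINS), (1.0 - sharpness) / N_DIST_BINS)
    np.put_along_axis(probs, bins[..., None], (1.0 - sharpness) / N_DIST_BINS + sharpness,
                      axis=-1)
    uniform_err = PairErrorMap(np.ones((L, L)))
    decoys = []
    for k in range(n):
        sigma = float(noise_scales[k % len(noise_scales)])
        w = min(0.5, 0.05 * sigma)
        perturbed = perturb_frames(frames, w, sigma, seed=seed + 7919 * k)
        # move each nucleotide's own atoms with its frame update (exact
        # identity at zero noise, unlike re-imposing the shared template)
        local = np.einsum("iba,ikb->ika", frames.rotations,
                          ref.coords - frames.translations[:, None, :])
        coords = np.einsum("iab,ikb->ika", perturbed.rotations, local) \
            + perturbed.translations[:, None, :]
        structure = CoarseStructure(coords, ref.sequence)
        decoys.append(Decoy(structure, Distogram(probs.copy()), uniform_err))
    return DecoyPool(decoys)
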