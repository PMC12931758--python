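"""Consensus decoy selection and optimization (the CSOR protocol).

Given a pool of N candidate conformations, each with a predicted distance
probability map (distogram) and optionally a pairwise error map, the
protocol:

1. **filters** (targets above 150 nt) decoys whose geometric base-pair count
   falls below 90 % of the pool maximum,
2. **scores** every decoy against the whole pool with a global consensus
   energy E_global = E_e2e + E_dist, where

       E_e2e(T)  = Σ_n gFAPE(T, T_n, w_n, ∞)
       E_dist(x) = −Σ_n Σ_{i≠j} Σ_{g∈channels}
                   log[(P_ij^{n,g}(d_ij^g) + 0.001) / (P_ij^{n,gM} + 0.001)]

   with gM the last bin below 40 Å (the reference state),
3. **selects** the 5 lowest-energy decoys and L-BFGS-optimizes frames under
   E_opt = E_global restricted to those 5,
4. **clusters** the pool (greedy neighbor clustering on pairwise P-atom
   RMSD with an adaptive cutoff) and optimizes each cluster center the same
   way, emitting up to 5 models ranked by E_opt.

For gradient-based optimization the binned E_dist is replaced by its linear
interpolation across bin centers (the exact binned form is piecewise
constant); scoring and ranking always use the exact binned form.  An
optional full-atom refinement hook may be configured; by default it is a
no-op.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import _autograd as ag
from ._autograd import Tensor
from .errors import IngestError
from .fold_losses import (DEFAULT_BINNING, DistanceBinning, GfapeParams,
                          GFAPE_EPSILON, bin_distances, gfape_tensors)
from .geometry import (CoarseStructure, DEFAULT_TEMPLATE, FrameSet,
                       LocalAtomTemplate, atoms_from_frames, frames_from_atoms,
                       symmetric_orthogonalize)
from .metrics import detect_base_pairs, kabsch_rmsd
from .networks import Distogram, PairErrorMap  # noqa: F401 (re-exported pool types)

__all__ = [
    "Decoy",
    "DecoyPool",
    "EnergyBreakdown",
    "CsorConfig",
    "e2e_energy",
    "dist_energy",
    "global_energy",
    "bp_count_filter",
    "select_models",
    "optimize_conformation",
    "cluster_decoys",
    "csor_pipeline",
]

DIST_PSEUDOCOUNT = 0.001
REFERENCE_BIN = 38  # last bin below the 40 Å threshold
BP_FILTER_MIN_LENGTH = 150
BP_FILTER_RATIO = 0.9


@dataclass
class Decoy:
    structure: CoarseStructure
    distogram: Distogram | None = None
    error_map: PairErrorMap | None = None
    _frames: FrameSet | None = field(default=None, repr=False)

    def frames(self, template: LocalAtomTemplate = DEFAULT_TEMPLATE) -> FrameSet:
        if self._frames is None:
            self._frames = frames_from_atoms(self.structure, template)
        return self._frames


@dataclass
class DecoyPool:
    """N decoy conformations sharing one sequence length."""

    decoys: list

    def __post_init__(self):
        if not self.decoys:
            raise IngestError("decoy pool must contain at least one decoy")
        self.decoys = [d if isinstance(d, Decoy) else Decoy(*d) for d in self.decoys]
        L = len(self.decoys[0].structure)
        for d in self.decoys:
            if len(d.structure) != L:
                raise IngestError("all pool members must share the sequence length")
            if d.distogram is not None and d.distogram.length != L:
                raise IngestError("distogram length mismatch in pool")
            if d.error_map is not None and d.error_map.weights.shape[0] != L:
                raise IngestError("error map length mismatch in pool")

    @property
    def length(self) -> int:
        return len(self.decoys[0].structure)

    def __len__(self):
        return len(self.decoys)

    def __iter__(self):
        return iter(self.decoys)


@dataclass(frozen=True)
class EnergyBreakdown:
    e2e: float
    dist: float

    @property
    def total(self) -> float:
        return self.e2e + self.dist

    def as_dict(self):
        return {"e2e": self.e2e, "dist": self.dist, "total": self.total}


@dataclass
class CsorConfig:
    select_k: int = 5
    max_models: int = 5
    cluster_cutoffs: tuple = (2.0, 4.0, 6.0, 8.0)
    cluster_top_fraction: float = 0.3
    max_clusters: int = 5
    lbfgs_maxiter: int = 150
    refine_hook: object = None          # callable CoarseStructure -> CoarseStructure
    template: LocalAtomTemplate = DEFAULT_TEMPLATE
    binning: DistanceBinning = DEFAULT_BINNING


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def _decoy_lambda(decoy: Decoy, L: int) -> np.ndarray:
    if decoy.error_map is not None:
        return decoy.error_map.weights
    return np.ones((L, L))


def _e2e_energy_t(rot, tr, pool: DecoyPool, template: LocalAtomTemplate):
    L = pool.length
    total = None
    for decoy in pool:
        fr = decoy.frames(template)
        params = GfapeParams(_decoy_lambda(decoy, L), np.full((L, L), np.inf))
        term = gfape_tensors(rot, tr, fr.rotations, fr.translations, params, template)
        total = term if total is None else total + term
    return total


def e2e_energy(conf: FrameSet, pool: DecoyPool,
               template: LocalAtomTemplate = DEFAULT_TEMPLATE) -> float:
    """Consensus end-to-end energy: summed unclamped gFAPE to every decoy,
    weighted per pair by the decoy's error map (uniform if absent)."""
    if len(conf) != pool.length:
        raise ValueError("conformation length does not match pool")
    with ag.no_grad():
        value = _e2e_energy_t(conf.rotations, conf.translations, pool, template)
    return float(value.data)


def _channel_distances(coords: np.ndarray) -> np.ndarray:
    """(3, L, L) pairwise distances per atom channel from (L, 3, 3) coords."""
    return np.linalg.norm(coords[:, None, :, :] - coords[None, :, :, :],
                          axis=-1).transpose(2, 0, 1)


def dist_energy(conf: CoarseStructure, pool: DecoyPool,
                binning: DistanceBinning = DEFAULT_BINNING) -> float:
    """Consensus distance energy (exact binned form; lower is better)."""
    if len(conf) != pool.length:
        raise ValueError("conformation length does not match pool")
    L = len(conf)
    bins = bin_distances(_channel_distances(conf.coords), binning)  # (3, L, L)
    off_diag = ~np.eye(L, dtype=bool)
    total = 0.0
    for decoy in pool:
        if decoy.distogram is None:
            continue
        p = decoy.distogram.probs  # (3, L, L, 40)
        picked = np.take_along_axis(p, bins[..., None], axis=-1)[..., 0]
        ref = p[..., REFERENCE_BIN]
        ratio = np.log((picked + DIST_PSEUDOCOUNT) / (ref + DIST_PSEUDOCOUNT))
        total -= ratio[:, off_diag].sum()
    return float(total)


def global_energy(conf, pool: DecoyPool,
                  template: LocalAtomTemplate = DEFAULT_TEMPLATE,
                  binning: DistanceBinning = DEFAULT_BINNING) -> EnergyBreakdown:
    """E_global = E_e2e + E_dist for a conformation given as a FrameSet or a
    CoarseStructure (the missing representation is derived via the template)."""
    if isinstance(conf, FrameSet):
        frames, coords = conf, atoms_from_frames(conf, template)
    else:
        frames, coords = frames_from_atoms(conf, template), conf
    return EnergyBreakdown(e2e=e2e_energy(frames, pool, template),
                           dist=dist_energy(coords, pool, binning))


# ---------------------------------------------------------------------------
# filtering, selection, clustering
# ---------------------------------------------------------------------------

def bp_count_filter(pool: DecoyPool, min_length: int = BP_FILTER_MIN_LENGTH,
                    ratio: float = BP_FILTER_RATIO) -> DecoyPool:
    """Drop decoys with fewer than 90 % of the maximum base-pair count.

    Applied only to targets longer than ``min_length`` nucleotides; the
    maximum-count decoy always survives, so the pool never empties.
    """
    if pool.length <= min_length:
        return pool
    counts = np.array([len(detect_base_pairs(d.structure)) for d in pool])
    keep = counts >= ratio * counts.max()
    return DecoyPool([d for d, k in zip(pool, keep) if k])


def select_models(pool: DecoyPool, k: int = 5,
                  template: LocalAtomTemplate = DEFAULT_TEMPLATE,
                  binning: DistanceBinning = DEFAULT_BINNING):
    """Indices and energies of the k lowest-E_global decoys (stable ties)."""
    if k > len(pool):
        warnings.warn(f"requested {k} models from a pool of {len(pool)}; returning all")
        k = len(pool)
    energies = [global_energy(d.structure, pool, template, binning) for d in pool]
    order = np.argsort([e.total for e in energies], kind="stable")[:k]
    return [int(i) for i in order], [energies[int(i)] for i in order]


def cluster_decoys(pool: DecoyPool, config: CsorConfig | None = None):
    """Greedy neighbor clustering on pairwise P-atom RMSD.

    The cutoff is adaptive: the smallest value in ``cluster_cutoffs`` whose
    densest neighborhood holds at least ``cluster_top_fraction`` of the pool
    (falling back to the largest cutoff).  Repeatedly the decoy with the most
    in-cutoff neighbors (ties: lowest index) becomes a center and its cluster
    is removed.  Returns the list of center indices.
    """
    config = config or CsorConfig()
    n = len(pool)
    if n == 1:
        return [0]
    rmsd = np.zeros((n, n))
    p_sets = [d.structure.p_atoms for d in pool]
    for i in range(n):
        for j in range(i + 1, n):
            rmsd[i, j] = rmsd[j, i] = kabsch_rmsd(p_sets[i], p_sets[j])
    cutoff = config.cluster_cutoffs[-1]
    for c in sorted(config.cluster_cutoffs):
        if (rmsd <= c).sum(axis=1).max() >= config.cluster_top_fraction * n:
            cutoff = c
            break
    remaining = list(range(n))
    centers = []
    while remaining and len(centers) < config.max_clusters:
        counts = [(sum(rmsd[i, j] <= cutoff for j in remaining), -i) for i in remaining]
        best = max(range(len(remaining)), key=lambda t: counts[t])
        center = remaining[best]
        centers.append(center)
        remaining = [j for j in remaining if rmsd[center, j] > cutoff]
    return centers


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

def _quats_to_rotations(q: Tensor) -> Tensor:
    """(L, 4) unnormalized quaternions (w, x, y, z) → (L, 3, 3) rotations."""
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    n2 = w * w + x * x + y * y + z * z
    s = 2.0 / n2
    one = Tensor(np.ones(w.shape))
    rows = [
        ag.stack([one - s * (y * y + z * z), s * (x * y - w * z), s * (x * z + w * y)], axis=-1),
        ag.stack([s * (x * y + w * z), one - s * (x * x + z * z), s * (y * z - w * x)], axis=-1),
        ag.stack([s * (x * z - w * y), s * (y * z + w * x), one - s * (x * x + y * y)], axis=-1),
    ]
    return ag.stack(rows, axis=-2)


def _smoothed_dist_energy_t(coords: Tensor, pool: DecoyPool, binning: DistanceBinning):
    """Linear interpolation of the binned consensus distance potential."""
    L = pool.length
    centers = binning.centers           # evenly spaced, step 1.0
    step = centers[1] - centers[0]
    # combined potential table V[c, i, j, g], summed over decoys with maps
    v = None
    for decoy in pool:
        if decoy.distogram is None:
            continue
        p = decoy.distogram.probs
        term = -np.log((p + DIST_PSEUDOCOUNT)
                       / (p[..., REFERENCE_BIN:REFERENCE_BIN + 1] + DIST_PSEUDOCOUNT))
        v = term if v is None else v + term
    if v is None:
        return Tensor(np.zeros(()))
    # pairwise distances per channel as tensors
    ii, jj = np.where(~np.eye(L, dtype=bool))
    total = None
    for c in range(3):
        xc = coords[:, c, :]
        diff = xc[ii] - xc[jj]
        d = ((diff * diff).sum(axis=-1) + 1e-12).sqrt()
        u = ag.minimum(ag.maximum(d - centers[0], 0.0), (len(centers) - 1) * step - 1e-9)
        k = np.floor(u.data / step).astype(np.int64)
        frac = u * (1.0 / step) - k
        v_lo = v[c, ii, jj, k]
        v_hi = v[c, ii, jj, np.minimum(k + 1, len(centers) - 1)]
        contrib = (Tensor(v_lo) + frac * Tensor(v_hi - v_lo)).sum()
        total = contrib if total is None else total + contrib
    return total


def _opt_objective_t(q: Tensor, t: Tensor, selected: DecoyPool, config: CsorConfig):
    rot = _quats_to_rotations(q)
    e2e = _e2e_energy_t(rot, t, selected, config.template)
    coords = ag.einsum("jab,kb->jka", rot, config.template.array) + t.reshape(len(selected.decoys[0].structure), 1, 3)
    dist = _smoothed_dist_energy_t(coords, selected, config.binning)
    return e2e + dist


def optimization_energy(frames: FrameSet, selected: DecoyPool,
                        config: CsorConfig | None = None) -> float:
    """E_opt as seen by the optimizer (smoothed distance term)."""
    config = config or CsorConfig()
    quat = _rotations_to_quats(frames.rotations)
    with ag.no_grad():
        value = _opt_objective_t(Tensor(quat), Tensor(frames.translations.copy()),
                                 selected, config)
    return float(value.data)


def _rotations_to_quats(rotations: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    q = Rotation.from_matrix(rotations).as_quat()  # (x, y, z, w)
    return np.stack([q[:, 3], q[:, 0], q[:, 1], q[:, 2]], axis=1)


def optimize_conformation(start: FrameSet, selected: DecoyPool,
                          config: CsorConfig | None = None) -> FrameSet:
    """L-BFGS refinement of frames under E_opt over the selected decoys.

    Frames are parameterized as per-nucleotide quaternion + translation;
    gradients come from the autodiff engine.  The returned conformation never
    has a higher E_opt than the start (the start is returned if the optimizer
    fails to improve it).
    """
    config = config or CsorConfig()
    if len(selected) > 5:
        warnings.warn("optimization pool larger than 5 decoys; using all of them")
    L = len(start)
    q0 = _rotations_to_quats(start.rotations)
    x0 = np.concatenate([q0.ravel(), start.translations.ravel()])

    def objective(x):
        q = Tensor(x[:4 * L].reshape(L, 4).copy(), requires_grad=True)
        t = Tensor(x[4 * L:].reshape(L, 3).copy(), requires_grad=True)
        value = _opt_objective_t(q, t, selected, config)
        value.backward()
        grad = np.concatenate([q.grad.ravel(), t.grad.ravel()])
        return float(value.data), grad

    f0, _ = objective(x0)
    if not np.isfinite(f0):
        raise ValueError("non-finite optimization energy at the starting point")
    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": config.lbfgs_maxiter})
    x_best, f_best = (res.x, res.fun) if res.fun <= f0 else (x0, f0)
    q = x_best[:4 * L].reshape(L, 4)
    t = x_best[4 * L:].reshape(L, 3).copy()
    rot = np.stack([symmetric_orthogonalize(m)
                    for m in _quats_to_rotations(Tensor(q)).data])
    return FrameSet(rot, t)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class CsorModel:
    structure: CoarseStructure
    frames: FrameSet
    energy: EnergyBreakdown
    source: str                        # "best" or "cluster<k>"


def csor_pipeline(pool: DecoyPool, config: CsorConfig | None = None):
    """Run filter → select → optimize (+ cluster centers) → rank.

    Returns up to ``max_models`` :class:`CsorModel` ordered by ascending
    E_opt; the first model has the lowest E_opt.  Cluster centers duplicating
    the best decoy are skipped.  The refinement hook, when configured, is
    applied to each final structure.
    """
    config = config or CsorConfig()
    filtered = bp_count_filter(pool)
    order, _ = select_models(filtered, config.select_k, config.template, config.binning)
    selected = DecoyPool([filtered.decoys[i] for i in order])

    candidates = [("best", order[0])]
    for rank, center in enumerate(cluster_decoys(filtered, config)):
        if center != order[0]:
            candidates.append((f"cluster{rank}", center))

    models = []
    sequence = filtered.decoys[0].structure.sequence
    for source, idx in candidates[:config.max_models]:
        start = filtered.decoys[idx].frames(config.template)
        opt = optimize_conformation(start, selected, config)
        # transport the decoy's own atoms with the frame update so the local
        # atom geometry survives (the template is internal to scoring)
        ref_coords = filtered.decoys[idx].structure.coords
        local = np.einsum("iba,ikb->ika", start.rotations,
                          ref_coords - start.translations[:, None, :])
        moved = np.einsum("iab,ikb->ika", opt.rotations, local) \
            + opt.translations[:, None, :]
        coords = CoarseStructure(moved, sequence)
        energy = global_energy(opt, selected, config.template, config.binning)
        if config.refine_hook is not None:
            coords = config.refine_hook(coords)
        models.append(CsorModel(coords, opt, energy, source))
    models.sort(key=lambda m: m.energy.total)
    return models[:config.max_models]
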