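"""Rigid-frame algebra for coarse-grained nucleotides.

Each nucleotide is represented by three atoms — the backbone phosphate P, the
sugar C4', and the glycosidic nitrogen of the base (N1 for pyrimidines, N9
for purines) — and by a rigid frame (rotation + translation) that maps a
shared local atom template into global coordinates.  This module provides:

* frame construction from observed atom triples by symmetric
  orthogonalization (the polar-decomposition rotation nearest the input in
  Frobenius norm),
* atom reconstruction from frames and the local template,
* geodesic rotation interpolation (slerp), and
* the denoising perturbation used during structure-module training: rotations
  are slerped toward an independent uniform random rotation with weight ``w``
  and translations receive additive Gaussian noise of scale ``sigma`` (the
  training defaults are ``w = 0.1`` and ``sigma = 0.1`` Å).

Conventions: rotations act on column vectors; coordinates are right-handed,
in Å.  Atom order is ``(P, C4', N)`` everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .errors import DegenerateInputError

__all__ = [
    "ATOM_NAMES",
    "RigidFrame",
    "FrameSet",
    "LocalAtomTemplate",
    "CoarseStructure",
    "DEFAULT_TEMPLATE",
    "symmetric_orthogonalize",
    "frames_from_atoms",
    "atoms_from_frames",
    "slerp_rotation",
    "perturb_frames",
    "random_rotation",
]

ATOM_NAMES = ("P", "C4'", "N")

_ORTHO_TOL = 1e-6


def _check_rotation(r: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {r.shape}")
    if not np.allclose(r.T @ r, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthogonal within tolerance")
    if not np.isclose(np.linalg.det(r), 1.0, atol=tol):
        raise ValueError("matrix determinant is not +1 within tolerance")


@dataclass(frozen=True)
class RigidFrame:
    """A rotation + translation; ``apply`` maps local to global coordinates."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float).reshape(3)
        _check_rotation(rot)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    @staticmethod
    def identity() -> "RigidFrame":
        return RigidFrame(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points of shape (..., 3) from local into global coordinates."""
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidFrame":
        rt = self.rotation.T
        return RigidFrame(rt, -rt @ self.translation)

    def compose(self, other: "RigidFrame") -> "RigidFrame":
        """Return self ∘ other (apply ``other`` first, then ``self``)."""
        return RigidFrame(self.rotation @ other.rotation,
                          self.rotation @ other.translation + self.translation)


@dataclass
class FrameSet:
    """An ordered collection of per-nucleotide rigid frames.

    Stored internally as stacked arrays ``rotations`` (L, 3, 3) and
    ``translations`` (L, 3) for vectorized math; :attr:`frames` gives the
    list-of-RigidFrame view.
    """

    rotations: np.ndarray
    translations: np.ndarray

    def __post_init__(self):
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        if self.rotations.ndim != 3 or self.rotations.shape[1:] != (3, 3):
            raise ValueError("rotations must have shape (L, 3, 3)")
        if self.translations.shape != (self.rotations.shape[0], 3):
            raise ValueError("translations must have shape (L, 3)")
        for r in self.rotations:
            _check_rotation(r)

    @staticmethod
    def from_frames(frames) -> "FrameSet":
        frames = list(frames)
        return FrameSet(np.stack([f.rotation for f in frames]),
                        np.stack([f.translation for f in frames]))

    @staticmethod
    def identity(length: int) -> "FrameSet":
        """Black-hole initialization: identity rotations, zero translations."""
        return FrameSet(np.broadcast_to(np.eye(3), (length, 3, 3)).copy(),
                        np.zeros((length, 3)))

    @property
    def frames(self):
        return [RigidFrame(r, t) for r, t in zip(self.rotations, self.translations)]

    def __len__(self) -> int:
        return self.rotations.shape[0]

    def transformed_by(self, g: RigidFrame) -> "FrameSet":
        """Compose one global rigid motion on the left of every frame."""
        return FrameSet(np.einsum("ab,ibc->iac", g.rotation, self.rotations),
                        self.translations @ g.rotation.T + g.translation)

    def copy(self) -> "FrameSet":
        return FrameSet(self.rotations.copy(), self.translations.copy())


@dataclass(frozen=True)
class LocalAtomTemplate:
    """The shared local conformation r⃗ of the three coarse atoms.

    The default (:data:`DEFAULT_TEMPLATE`) is the package's idealized
    coarse-grained nucleotide, parametrized to be consistent with the
    synthetic-structure generator: with an 19 Å strand separation it yields
    a 9.0 Å glycosidic N–N distance across a base pair.  One template is
    shared across the four nucleotide types; it is an explicit argument of
    every operation that needs it, so alternative geometries are drop-in.
    """

    atoms: np.ndarray  # (3, 3): rows P, C4', N

    def __post_init__(self):
        arr = np.asarray(self.atoms, dtype=float)
        if arr.shape != (3, 3):
            raise ValueError("template must contain exactly three 3D points (P, C4', N)")
        d = np.linalg.norm(arr[:, None, :] - arr[None, :, :], axis=-1)
        off = d[~np.eye(3, dtype=bool)]
        if np.any(off <= 0.0) or np.any(off >= 10.0):
            raise ValueError("template pairwise distances must be in (0, 10) Å")
        object.__setattr__(self, "atoms", arr)

    @property
    def array(self) -> np.ndarray:
        return self.atoms


DEFAULT_TEMPLATE = LocalAtomTemplate(np.array([
    [0.0, 0.0, 0.0],   # P
    [1.6, 0.0, 1.3],   # C4'
    [5.0, 0.0, 0.0],   # N (glycosidic N1/N9), pointing toward the pairing partner
]))


@dataclass
class CoarseStructure:
    """L nucleotides × 3 atoms (P, C4', N) × xyz coordinates in Å."""

    coords: np.ndarray
    sequence: str | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (3, 3):
            raise ValueError("coords must have shape (L, 3, 3)")
        if np.isnan(self.coords).any():
            raise ValueError("coords contain NaN")
        if self.sequence is not None:
            if len(self.sequence) != self.coords.shape[0]:
                raise ValueError("sequence length does not match coordinate count")
            if set(self.sequence) - set("ACGU"):
                raise ValueError("sequence must be over {A, C, G, U}")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def p_atoms(self) -> np.ndarray:
        return self.coords[:, 0, :]

    @property
    def c4_atoms(self) -> np.ndarray:
        return self.coords[:, 1, :]

    @property
    def n_atoms(self) -> np.ndarray:
        return self.coords[:, 2, :]

    def transformed_by(self, g: RigidFrame) -> "CoarseStructure":
        return CoarseStructure(g.apply(self.coords), self.sequence)

    def copy(self) -> "CoarseStructure":
        return CoarseStructure(self.coords.copy(), self.sequence)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def symmetric_orthogonalize(m: np.ndarray) -> np.ndarray:
    """Project a full-rank 3×3 matrix onto the nearest rotation.

    Computes the polar factor ``m (mᵀm)^(-1/2)`` via eigendecomposition of
    the symmetric Gram matrix; for ``det(m) > 0`` this is the rotation
    closest to ``m`` in Frobenius norm.

    Raises
    ------
    DegenerateInputError
        If ``m`` is singular (to numerical tolerance) or has non-positive
        determinant (reflection-dominant input).
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {m.shape}")
    det = np.linalg.det(m)
    if det <= 0.0:
        raise DegenerateInputError(f"matrix determinant {det:.3e} is not positive")
    w, v = np.linalg.eigh(m.T @ m)
    if w[0] <= 1e-12 * max(w[-1], 1.0):
        raise DegenerateInputError("matrix is numerically singular")
    inv_sqrt = (v * (w ** -0.5)) @ v.T
    r = m @ inv_sqrt
    # numerical cleanup: one more polar step costs nothing at 3x3
    u, _, vt = np.linalg.svd(r)
    return u @ vt


def frames_from_atoms(s: CoarseStructure, template: LocalAtomTemplate = DEFAULT_TEMPLATE) -> FrameSet:
    """Fit one rigid frame per nucleotide by least squares.

    For each nucleotide the returned frame minimizes the squared error of
    mapping the template atoms onto the observed atoms (Kabsch on the three
    centered points; a centered 3-point set is planar, so the rank-aware
    proper-rotation construction is used rather than the full-rank polar
    projection).  The translation aligns the centroids.
    """
    tmpl = template.array
    tmpl_c = tmpl - tmpl.mean(axis=0)
    rotations = np.empty((len(s), 3, 3))
    translations = np.empty((len(s), 3))
    for i, obs in enumerate(s.coords):
        v1 = obs[1] - obs[0]
        v2 = obs[2] - obs[0]
        cross = np.cross(v1, v2)
        if np.linalg.norm(cross) < 1e-8 * max(np.linalg.norm(v1) * np.linalg.norm(v2), 1.0):
            raise DegenerateInputError(f"nucleotide {i}: atom triple is collinear")
        obs_c = obs - obs.mean(axis=0)
        r = Rotation.align_vectors(obs_c, tmpl_c)[0].as_matrix()
        rotations[i] = r
        translations[i] = obs.mean(axis=0) - r @ tmpl.mean(axis=0)
    return FrameSet(rotations, translations)


def atoms_from_frames(t: FrameSet, template: LocalAtomTemplate = DEFAULT_TEMPLATE,
                      sequence: str | None = None) -> CoarseStructure:
    """Place the template atoms with every frame: coords[j, k] = R_j r_k + t_j."""
    coords = np.einsum("jab,kb->jka", t.rotations, template.array) + t.translations[:, None, :]
    return CoarseStructure(coords, sequence)


def slerp_rotation(a: np.ndarray, b: np.ndarray, w: float) -> np.ndarray:
    """Geodesic interpolation between rotations ``a`` (w=0) and ``b`` (w=1)."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"interpolation weight must lie in [0, 1], got {w}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_rotation(a)
    _check_rotation(b)
    if w == 0.0:
        return a.copy()
    if w == 1.0:
        return b.copy()
    key = Rotation.from_matrix(np.stack([a, b]))
    return Slerp([0.0, 1.0], key)(w).as_matrix()


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation sampled via a normalized 4D Gaussian quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def perturb_frames(t: FrameSet, w: float, sigma: float, seed: int) -> FrameSet:
    """Denoising perturbation of a frame set.

    Each rotation is replaced by ``slerp(R_i, R_random, w)`` with an
    independently sampled uniform random rotation; each translation gets
    additive isotropic Gaussian noise of scale ``sigma`` Å.  Deterministic
    given ``seed``.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"rotation noise weight must lie in [0, 1], got {w}")
    if sigma < 0.0:
        raise ValueError(f"translation noise scale must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    rotations = np.empty_like(t.rotations)
    translations = np.empty_like(t.translations)
    for i in range(len(t)):
        r_random = random_rotation(rng)
        rotations[i] = slerp_rotation(t.rotations[i], r_random, w)
        translations[i] = t.translations[i] + rng.normal(0.0, sigma, size=3) if sigma > 0 \
            else t.translations[i]
    return FrameSet(rotations, translations)
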