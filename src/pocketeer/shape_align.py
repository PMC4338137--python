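"""Gaussian shape/chemistry overlap alignment and Tanimoto scoring.

Molecular shape is modeled as a sum of spherical Gaussians, one per atom,
in the Grant–Pickup parameterization: amplitude p = 2.828 and exponent
chosen so that an isolated atom's Gaussian integral equals its hard-sphere
volume (4/3)πr³.  The overlap between two sets is the first-order
(pairwise) analytic integral of the product densities, which for Gaussians

    ∫ p·e^{-α_i|r-c_i|²} · p·e^{-α_j|r-c_j|²} dr
        = p² (π/(α_i+α_j))^{3/2} · e^{-α_iα_j d²/(α_i+α_j)}

is exact for the summed densities.  Chemistry ("color") is scored the same
way over matched polar features only (donor–donor, acceptor–acceptor) with
fixed-radius color Gaussians.  Alignment maximizes
shape + color_weight·color overlap over the 6 rigid degrees of freedom from
principal-axes and seeded random starts, and the exemplar distance is
2 − (shape Tanimoto + color Tanimoto) of the best pose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .structure_io import ACCEPTOR, DONOR, TypedAtomSet

logger = logging.getLogger(__name__)

#: Grant–Pickup Gaussian amplitude (2·√2).
GAUSS_AMPLITUDE = 2.828

COLOR_FEATURES = (DONOR, ACCEPTOR)
COLOR_RADIUS = 1.0  # Å, fixed radius of color Gaussians


def gaussian_alpha(radius: np.ndarray | float, p: float = GAUSS_AMPLITUDE) -> np.ndarray:
    """Exponent α such that p·(π/α)^{3/2} = (4/3)π r³."""
    r = np.asarray(radius, dtype=float)
    return np.pi * (3.0 * p / (4.0 * np.pi * r ** 3)) ** (2.0 / 3.0)


@dataclass
class RigidTransform:
    rotation: np.ndarray      # (3,3) proper orthonormal
    translation: np.ndarray   # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation is not proper (det != +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def random(cls, rng: np.random.Generator, max_translation: float = 10.0) -> "RigidTransform":
        t = rng.uniform(-max_translation, max_translation, 3)
        return cls(_random_rotation(rng), t)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


@dataclass
class OverlapScore:
    shape_overlap: float
    self_overlap_a: float
    self_overlap_b: float
    shape_tanimoto: float
    color_tanimoto: float

    @property
    def tanimoto_combo(self) -> float:
        return self.shape_tanimoto + self.color_tanimoto

    @property
    def distance(self) -> float:
        return 2.0 - self.tanimoto_combo

    def __post_init__(self) -> None:
        assert -1e-9 <= self.shape_tanimoto <= 1 + 1e-9, self.shape_tanimoto
        assert -1e-9 <= self.color_tanimoto <= 1 + 1e-9, self.color_tanimoto
        self.shape_tanimoto = float(np.clip(self.shape_tanimoto, 0.0, 1.0))
        self.color_tanimoto = float(np.clip(self.color_tanimoto, 0.0, 1.0))


@dataclass
class AlignConfig:
    color_weight: float = 0.5        # weight of color overlap in the objective
    include_hydrophobe_color: bool = False
    n_random_starts: int = 6         # extra seeded random-rotation starts
    max_evals: int = 300             # objective evaluations per start
    tol: float = 1e-4
    seed: int = 17


def _pair_overlap_matrix_consts(alpha_a: np.ndarray, alpha_b: np.ndarray,
                                p: float = GAUSS_AMPLITUDE):
    """Per-pair prefactor and exponent coefficient for the analytic integral."""
    s = alpha_a[:, None] + alpha_b[None, :]
    pref = p * p * (np.pi / s) ** 1.5
    coef = alpha_a[:, None] * alpha_b[None, :] / s
    return pref, coef


def _overlap_from_positions(pos_a, alpha_a, pos_b, alpha_b, p=GAUSS_AMPLITUDE) -> float:
    if len(pos_a) == 0 or len(pos_b) == 0:
        return 0.0
    pref, coef = _pair_overlap_matrix_consts(alpha_a, alpha_b, p)
    d2 = np.sum((pos_a[:, None, :] - pos_b[None, :, :]) ** 2, axis=2)
    return float(np.sum(pref * np.exp(-coef * d2)))


def gaussian_overlap(a: TypedAtomSet, b: TypedAtomSet,
                     transform: RigidTransform | None = None) -> float:
    """First-order analytic Gaussian shape-overlap volume (Å³) between A and
    the transformed B."""
    pos_b = b.positions if transform is None else transform.apply(b.positions)
    return _overlap_from_positions(a.positions, gaussian_alpha(a.radii),
                                   pos_b, gaussian_alpha(b.radii))


def _color_positions(s: TypedAtomSet, config: AlignConfig) -> dict[str, np.ndarray]:
    feats = set(COLOR_FEATURES)
    if config.include_hydrophobe_color:
        feats.add("hydrophobe")
    out = {}
    for f in feats:
        mask = np.array([x == f for x in s.features], dtype=bool)
        out[f] = s.positions[mask]
    return out


def color_overlap(a: TypedAtomSet, b: TypedAtomSet,
                  transform: RigidTransform | None = None,
                  config: AlignConfig | None = None) -> tuple[dict[str, float], float]:
    """Per-feature color overlaps and the color Tanimoto.

    Color is computed over matched polar features only (ROCS convention:
    hydrophobes contribute to shape, not color) with fixed-radius Gaussians.
    If neither set carries color features the color Tanimoto is 1 (vacuous
    agreement: two purely apolar sets have identical, empty, chemistry); if
    exactly one side has color it is 0.
    """
    config = config or AlignConfig()
    t = transform or RigidTransform.identity()
    ca, cb = _color_positions(a, config), _color_positions(b, config)
    alpha = gaussian_alpha(np.array([COLOR_RADIUS]))
    per_feature: dict[str, float] = {}
    o_ab = o_aa = o_bb = 0.0
    for f in ca:
        pa, pb = ca[f], t.apply(cb[f]) if len(cb[f]) else cb[f]
        al_a = np.full(len(pa), alpha[0])
        al_b = np.full(len(pb), alpha[0])
        per_feature[f] = _overlap_from_positions(pa, al_a, pb, al_b)
        o_ab += per_feature[f]
        o_aa += _overlap_from_positions(pa, al_a, pa, al_a)
        o_bb += _overlap_from_positions(pb, al_b, pb, al_b)
    denom = o_aa + o_bb - o_ab
    tanimoto = o_ab / denom if denom > 1e-12 else 1.0
    return per_feature, float(tanimoto)


class _PairEvaluator:
    """Precomputed overlap machinery for one (A, B) pair.

    B is parameterized as R(w)·R0·(B − cB) + cA + t with w a rotation vector
    and t a translation, so each objective evaluation is one pairwise
    distance matrix per channel.
    """

    def __init__(self, a: TypedAtomSet, b: TypedAtomSet, config: AlignConfig):
        self.config = config
        self.pos_a = a.positions
        self.alpha_a = gaussian_alpha(a.radii)
        self.pos_b = b.positions
        self.alpha_b = gaussian_alpha(b.radii)
        self.centroid_a = self.pos_a.mean(axis=0)
        self.centroid_b = self.pos_b.mean(axis=0)
        self.shape_pref, self.shape_coef = _pair_overlap_matrix_consts(
            self.alpha_a, self.alpha_b)
        self.self_a = _overlap_from_positions(self.pos_a, self.alpha_a,
                                              self.pos_a, self.alpha_a)
        self.self_b = _overlap_from_positions(self.pos_b, self.alpha_b,
                                              self.pos_b, self.alpha_b)
        ca = _color_positions(a, config)
        cb = _color_positions(b, config)
        self.color_alpha = float(gaussian_alpha(np.array([COLOR_RADIUS]))[0])
        self.color_pairs = []
        self.color_self_a = self.color_self_b = 0.0
        for f in ca:
            al = np.full(len(ca[f]), self.color_alpha)
            bl = np.full(len(cb[f]), self.color_alpha)
            self.color_self_a += _overlap_from_positions(ca[f], al, ca[f], al)
            self.color_self_b += _overlap_from_positions(cb[f], bl, cb[f], bl)
            if len(ca[f]) and len(cb[f]):
                pref, coef = _pair_overlap_matrix_consts(al, bl)
                self.color_pairs.append((ca[f], cb[f], pref, coef))

    def pose(self, params: np.ndarray, r0: np.ndarray) -> RigidTransform:
        w, t = params[:3], params[3:]
        rot = Rotation.from_rotvec(w).as_matrix() @ r0
        trans = self.centroid_a + t - rot @ self.centroid_b
        return RigidTransform(rot, trans)

    def overlaps(self, params: np.ndarray, r0: np.ndarray) -> tuple[float, float]:
        w, t = params[:3], params[3:]
        rot = Rotation.from_rotvec(w).as_matrix() @ r0
        shift = self.centroid_a + t - rot @ self.centroid_b
        pos_b = self.pos_b @ rot.T + shift
        d2 = np.sum((self.pos_a[:, None, :] - pos_b[None, :, :]) ** 2, axis=2)
        shape = float(np.sum(self.shape_pref * np.exp(-self.shape_coef * d2)))
        color = 0.0
        for pa, pb0, pref, coef in self.color_pairs:
            pb = pb0 @ rot.T + shift
            c2 = np.sum((pa[:, None, :] - pb[None, :, :]) ** 2, axis=2)
            color += float(np.sum(pref * np.exp(-coef * c2)))
        return shape, color

    def score(self, params: np.ndarray, r0: np.ndarray) -> OverlapScore:
        shape, color = self.overlaps(params, r0)
        shape_t = shape / (self.self_a + self.self_b - shape)
        cd = self.color_self_a + self.color_self_b - color
        color_t = color / cd if cd > 1e-12 else 1.0
        return OverlapScore(shape, self.self_a, self.self_b, shape_t, color_t)


def _principal_axes(points: np.ndarray) -> np.ndarray:
    """Proper-rotation matrix whose columns are the principal axes, largest
    variance first."""
    c = points - points.mean(axis=0)
    cov = c.T @ c / max(len(points), 1)
    vals, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return vecs


def _start_rotations(a: TypedAtomSet, b: TypedAtomSet, config: AlignConfig) -> list[np.ndarray]:
    ea = _principal_axes(a.positions)
    eb = _principal_axes(b.positions)
    starts = []
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        s = np.diag([sx, sy, sx * sy])  # proper sign combinations
        starts.append(ea @ s @ eb.T)
    rng = np.random.default_rng(config.seed)
    for _ in range(config.n_random_starts):
        starts.append(_random_rotation(rng))
    return starts


def align(a: TypedAtomSet, b: TypedAtomSet,
          config: AlignConfig | None = None) -> tuple[RigidTransform, OverlapScore]:
    """Find the near-optimal rigid alignment of B onto A.

    Starting poses superpose centroids and combine the four proper
    principal-axes sign flips with seeded random rotations; each start is
    refined by derivative-free (Nelder–Mead) maximization of
    shape + color_weight·color overlap.  Deterministic for a fixed config.
    """
    if len(a) < 1 or len(b) < 1:
        raise ValueError("cannot align empty atom sets")
    config = config or AlignConfig()
    ev = _PairEvaluator(a, b, config)

    def negative_objective(params, r0):
        shape, color = ev.overlaps(params, r0)
        return -(shape + config.color_weight * color)

    best_params, best_r0, best_val = None, None, np.inf
    x0 = np.zeros(6)
    for r0 in _start_rotations(a, b, config):
        res = minimize(
            negative_objective, x0, args=(r0,), method="Nelder-Mead",
            options={"maxfev": config.max_evals, "xatol": config.tol,
                     "fatol": config.tol, "adaptive": False},
        )
        if res.fun < best_val:
            best_val, best_params, best_r0 = res.fun, res.x, r0
    transform = ev.pose(best_params, best_r0)
    return transform, ev.score(best_params, best_r0)


def exemplar_distance(a: TypedAtomSet, b: TypedAtomSet,
                      config: AlignConfig | None = None) -> float:
    """Dissimilarity 2 − TanimotoCombo of the best alignment, evaluated in
    both directions (A onto B and B onto A) and taking the smaller."""
    config = config or AlignConfig()
    _, s_ab = align(a, b, config)
    _, s_ba = align(b, a, config)
    d = min(s_ab.distance, s_ba.distance)
    assert -1e-9 <= d <= 2 + 1e-9
    return float(np.clip(d, 0.0, 2.0))
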