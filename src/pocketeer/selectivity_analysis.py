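"""Selectivity analytics over exemplar distances.

Turns pairwise exemplar distances into the downstream readouts: all-vs-all
distance matrices, classical MDS "pocket space" maps, per-conformation
distinctness (how unique a sampled pocket is to one family member), per-
reference selectivity Z-score rows, ROC/Mann-Whitney evaluation against
binding classes, and Spearman correlation between similarity matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .shape_align import AlignConfig, exemplar_distance
from .structure_io import TypedAtomSet
from .exemplar import Exemplar

logger = logging.getLogger(__name__)

BINDING_CLASSES = ("strong", "medium", "weak", "none", "unknown")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=5e-3):
            raise ValueError("matrix is not symmetric within tolerance")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class SelectivityRow:
    reference_id: str
    protein_ids: list[str]
    min_distances: np.ndarray
    z_scores: np.ndarray
    labels: dict[str, str] = field(default_factory=dict)
    degenerate: bool = False


@dataclass
class DistinctnessValue:
    protein_id: str
    conformation_id: int
    d_other: float
    d_self: float

    @property
    def distinctness(self) -> float:
        return self.d_other - self.d_self


def _atoms_of(x) -> TypedAtomSet:
    return x.atoms if isinstance(x, Exemplar) else x


def distance_matrix(exemplars: list, labels: list[str] | None = None,
                    config: AlignConfig | None = None) -> DistanceMatrix:
    """All-vs-all exemplar distances; each pair is evaluated in both
    alignment directions and the smaller distance is kept, so the matrix is
    symmetric by construction."""
    if len(exemplars) < 2:
        raise ValueError("need at least 2 exemplars")
    labels = labels or [f"ex{i}" for i in range(len(exemplars))]
    n = len(exemplars)
    d = np.zeros((n, n))
    failures = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = exemplar_distance(
                    _atoms_of(exemplars[i]), _atoms_of(exemplars[j]), config)
            except Exception as exc:  # pragma: no cover - defensive
                failures.append((labels[i], labels[j], str(exc)))
                d[i, j] = d[j, i] = np.nan
    if failures:
        raise RuntimeError(f"alignment failed for pairs: {failures}")
    return DistanceMatrix(labels, d)


def classical_mds(dm: DistanceMatrix, dim: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared-distance matrix and embeds on the top
    eigenvectors scaled by root-eigenvalues.  Axis signs follow a fixed
    convention (first nonzero coordinate positive) for reproducible maps.
    """
    d2 = dm.values ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, dim))
    for k in range(min(dim, n)):
        if vals[k] > 1e-12:
            axis = vecs[:, k] * np.sqrt(vals[k])
            nz = np.nonzero(np.abs(axis) > 1e-12)[0]
            if len(nz) and axis[nz[0]] < 0:
                axis = -axis
            coords[:, k] = axis
    return pd.DataFrame(coords, index=dm.labels,
                        columns=[f"mds{k + 1}" for k in range(dim)])


def distinctness(membership: dict[str, list[int]], dm: DistanceMatrix) -> list[DistinctnessValue]:
    """Per-conformation distinctness within a family.

    ``membership`` maps protein id -> indices into the distance matrix of
    that protein's conformations.  For each conformation, d_other is the
    distance to the closest pocket of any *other* protein, d_self the
    distance to the closest *other* pocket of its own ensemble, and
    distinctness = d_other − d_self.
    """
    if len(membership) < 2:
        raise ValueError("need at least 2 proteins")
    for pid, idxs in membership.items():
        if len(idxs) < 2:
            raise ValueError(f"protein {pid!r} has fewer than 2 conformations")
    out: list[DistinctnessValue] = []
    for pid, idxs in membership.items():
        others = np.array(
            [i for q, ix in membership.items() if q != pid for i in ix], dtype=int)
        own = np.array(idxs, dtype=int)
        for i in idxs:
            d_other = float(dm.values[i, others].min())
            d_self = float(dm.values[i, own[own != i]].min())
            out.append(DistinctnessValue(pid, i, d_other, d_self))
    return out


def selectivity_row(reference, ensembles: dict[str, list],
                    reference_id: str = "ref",
                    labels: dict[str, str] | None = None,
                    config: AlignConfig | None = None) -> SelectivityRow:
    """Minimum exemplar distance from a reference (inhibitor-bound pocket
    exemplar, or the ligand conformer itself) to each protein's ensemble,
    normalized to Z-scores across the row (population SD).  Lower z means a
    closer pocket match, hence a predicted binder."""
    ref = _atoms_of(reference)
    protein_ids = list(ensembles)
    mins = []
    for pid in protein_ids:
        exs = ensembles[pid]
        if len(exs) == 0:
            raise ValueError(f"ensemble for {pid!r} is empty")
        mins.append(min(exemplar_distance(ref, _atoms_of(e), config) for e in exs))
    mins = np.array(mins)
    sd = float(mins.std())  # population SD
    degenerate = sd < 1e-12
    z = np.zeros_like(mins) if degenerate else (mins - mins.mean()) / sd
    if degenerate:
        logger.warning("selectivity row %s has no variation; z set to 0", reference_id)
    return SelectivityRow(reference_id, protein_ids, mins, z,
                          labels=labels or {}, degenerate=degenerate)


def roc_evaluate(rows: list[SelectivityRow],
                 positive: str = "strong", negative: str = "none"):
    """ROC over labeled cells: positives should have *lower* z than
    negatives.  AUC via the rank-sum identity; p from the tie-corrected
    normal-approximated Mann-Whitney U (one-sided).
    Returns (auc, p_value, curve) where curve is (fpr, tpr) points.
    """
    pos_scores, neg_scores = [], []
    for row in rows:
        for pid, z in zip(row.protein_ids, row.z_scores):
            cls = row.labels.get(pid, "unknown")
            if cls == positive:
                pos_scores.append(z)
            elif cls == negative:
                neg_scores.append(z)
    if not pos_scores or not neg_scores:
        raise ValueError("need at least one positive and one negative labeled cell")
    pos, neg = np.array(pos_scores), np.array(neg_scores)
    # lower z ranks first: test that neg > pos
    u_res = stats.mannwhitneyu(neg, pos, alternative="greater", method="asymptotic")
    auc = float(u_res.statistic / (len(pos) * len(neg)))
    scores = np.concatenate([pos, neg])
    truth = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    order = np.argsort(scores, kind="stable")
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    for i in order:
        if truth[i]:
            tp += 1
        else:
            fp += 1
        tpr.append(tp / len(pos))
        fpr.append(fp / len(neg))
    return auc, float(u_res.pvalue), (np.array(fpr), np.array(tpr))


def spearman_matrix_corr(m1: DistanceMatrix | np.ndarray,
                         m2: DistanceMatrix | np.ndarray) -> tuple[float, float]:
    """Spearman rho (and t-approximation p) between the vectorized upper
    triangles of two same-shaped similarity/distance matrices."""
    a = m1.values if isinstance(m1, DistanceMatrix) else np.asarray(m1, dtype=float)
    b = m2.values if isinstance(m2, DistanceMatrix) else np.asarray(m2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and same shape")
    iu = np.triu_indices(a.shape[0], k=1)
    rho, p = stats.spearmanr(a[iu], b[iu])
    return float(rho), float(p)
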