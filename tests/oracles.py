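"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives a quantity from its definition (double loops,
per-line scans, union-find, numerical quadrature, exhaustive grids) without
sharing code with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np

from pocketeer.pocket_detection import DEEP_POCKET, POCKET, PROTEIN, SOLVENT


def classify_oracle(origin, spacing, dims, positions, radii) -> np.ndarray:
    """O(atoms x points) double loop over every grid point and atom."""
    labels = np.full(dims, SOLVENT, dtype=np.int8)
    for ix in range(dims[0]):
        for iy in range(dims[1]):
            for iz in range(dims[2]):
                p = np.asarray(origin) + np.array([ix, iy, iz]) * spacing
                for pos, r in zip(positions, radii):
                    if np.linalg.norm(p - pos) <= r:
                        labels[ix, iy, iz] = PROTEIN
                        break
    return labels


def _lines(dims, d):
    """All maximal lattice lines along direction d (start points with p-d
    outside the grid)."""
    pts = np.indices(dims).reshape(3, -1).T
    for p in pts:
        q = p - np.asarray(d)
        if np.all((q >= 0) & (q < dims)):
            continue
        line = []
        cur = p.copy()
        while np.all((cur >= 0) & (cur < dims)):
            line.append(tuple(cur))
            cur = cur + d
        yield line


def mark_oracle(labels, directions, min_bounded) -> np.ndarray:
    """Per-line two-pointer scan for protein-bounded solvent runs."""
    dims = labels.shape
    count = np.zeros(dims, dtype=int)
    for d in directions:
        for line in _lines(dims, d):
            vals = [labels[p] for p in line]
            i = 0
            while i < len(vals):
                if vals[i] != SOLVENT:
                    i += 1
                    continue
                j = i
                while j < len(vals) and vals[j] == SOLVENT:
                    j += 1
                left_ok = i > 0 and vals[i - 1] == PROTEIN
                right_ok = j < len(vals) and vals[j] == PROTEIN
                if left_ok and right_ok:
                    for k in range(i, j):
                        count[line[k]] += 1
                i = j
    out = labels.copy()
    out[(labels == SOLVENT) & (count >= min_bounded)] = POCKET
    return out


def deep_oracle(labels, spacing, burial) -> np.ndarray:
    """All-pairs distance check from every pocket point to every solvent point."""
    out = labels.copy()
    solvent = np.argwhere(labels == SOLVENT)
    pockets = np.argwhere(labels == POCKET)
    for p in pockets:
        if len(solvent) == 0:
            out[tuple(p)] = DEEP_POCKET
            continue
        dmin = np.min(np.linalg.norm((solvent - p) * spacing, axis=1))
        if dmin > burial:
            out[tuple(p)] = DEEP_POCKET
    return out


class UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def components_oracle(mask) -> list[frozenset]:
    """Union-find over 26-neighbor adjacency of True cells."""
    pts = [tuple(p) for p in np.argwhere(mask)]
    index = {p: i for i, p in enumerate(pts)}
    uf = UnionFind(len(pts))
    for p in pts:
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if dx == dy == dz == 0:
                        continue
                    q = (p[0] + dx, p[1] + dy, p[2] + dz)
                    if q in index:
                        uf.union(index[p], index[q])
    groups = {}
    for p, i in index.items():
        groups.setdefault(uf.find(i), set()).add(p)
    return [frozenset(g) for g in groups.values()]


def single_linkage_oracle(positions, threshold) -> list[frozenset]:
    """Union-find over the full pairwise distance matrix."""
    n = len(positions)
    uf = UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(positions[i] - positions[j]) <= threshold:
                uf.union(i, j)
    groups = {}
    for i in range(n):
        groups.setdefault(uf.find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


def quadrature_overlap(pos_a, rad_a, pos_b, rad_b, h=0.1, pad=4.5,
                       p=2.828) -> float:
    """Midpoint-rule integral of the product of the two summed Gaussian
    densities on an h-spaced grid."""
    def alpha(r):
        return np.pi * (3.0 * p / (4.0 * np.pi * r ** 3)) ** (2.0 / 3.0)

    allpos = np.vstack([pos_a, pos_b])
    lo = allpos.min(axis=0) - pad
    hi = allpos.max(axis=0) + pad
    axes = [np.arange(lo[k] + h / 2, hi[k], h) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def density(pos, rad):
        rho = np.zeros(len(pts))
        for c, r in zip(pos, rad):
            d2 = np.sum((pts - c) ** 2, axis=1)
            rho += p * np.exp(-alpha(r) * d2)
        return rho

    return float(np.sum(density(pos_a, rad_a) * density(pos_b, rad_b)) * h ** 3)


def rotation_grid_best_overlap(a, b, objective, step_deg=10.0) -> float:
    """Exhaustive Euler-angle rotation grid about superposed centroids."""
    from scipy.spatial.transform import Rotation

    from pocketeer.shape_align import RigidTransform

    ca = a.positions.mean(axis=0)
    cb = b.positions.mean(axis=0)
    best = -np.inf
    step = np.deg2rad(step_deg)
    alphas = np.arange(0, 2 * np.pi, step)
    betas = np.arange(0, np.pi + 1e-9, step)
    gammas = np.arange(0, 2 * np.pi, step)
    for al in alphas:
        for be in betas:
            for ga in gammas:
                rot = Rotation.from_euler("zyz", [al, be, ga]).as_matrix()
                t = RigidTransform(rot, ca - rot @ cb)
                best = max(best, objective(t))
    return best


def auc_pair_count_oracle(pos_scores, neg_scores) -> float:
    """Fraction of (positive, negative) pairs ranked correctly (lower score
    = more positive), ties counted half."""
    wins = ties = 0
    for p in pos_scores:
        for n in neg_scores:
            if p < n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


def spearman_oracle(x, y) -> float:
    """Rank (average ranks for ties) then Pearson."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        pos = 0
        while pos < len(v):
            j = pos
            while j < len(v) and sorted_v[j] == sorted_v[pos]:
                j += 1
            avg = (pos + j - 1) / 2 + 1
            for k in range(pos, j):
                r[order[k]] = avg
            pos = j
        return r

    rx, ry = ranks(x), ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])
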