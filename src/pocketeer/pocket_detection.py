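"""Ligsite-style local pocket detection on a grid anchored at target residues.

A cubic grid is centered at the center of mass of one or two target
residues.  Points covered by the protein van der Waals surface are labeled
``protein``, the rest ``solvent``.  Along a fixed set of lattice scan
directions, maximal runs of solvent points bounded by protein at both ends
are counted; points bounded in at least ``min_bounded_directions``
directions become ``pocket``.  Pocket points more than ``burial_distance``
(default 2.5 Å, strictly) from every remaining solvent point form the
``deep_pocket`` set whose volume is the druggability-relevant "deep volume".
Pocket points are clustered (26-connectivity) and clusters not in direct
contact with the target residues are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .structure_io import Structure

# point labels
SOLVENT = 0
PROTEIN = 1
POCKET = 2
DEEP_POCKET = 3

#: The classic Ligsite scan set: 3 axes + 4 body diagonals.
LIGSITE_DIRECTIONS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


@dataclass
class GridParams:
    """Geometry of the pocket grid and the pocket/deep labeling rules."""

    edge_length: float = 24.0   # Å, cube edge
    spacing: float = 0.5        # Å between lattice points
    scan_directions: tuple[tuple[int, int, int], ...] = LIGSITE_DIRECTIONS
    min_bounded_directions: int = 1
    burial_distance: float = 2.5  # Å; deep iff dist to solvent > this (strict)
    contact_margin: float = 1.0   # Å added to atom vdW radius for target contact

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.edge_length < 4 * self.spacing:
            raise ValueError("edge_length must be at least 4 spacings")
        if self.burial_distance <= 0:
            raise ValueError("burial_distance must be positive")
        if self.min_bounded_directions < 1:
            raise ValueError("min_bounded_directions must be >= 1")


@dataclass
class PocketGrid:
    origin: np.ndarray           # (3,) Å, position of grid point [0,0,0]
    spacing: float
    dims: tuple[int, int, int]
    labels: np.ndarray           # (nx, ny, nz) int8
    target_residues: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.shape != tuple(self.dims):
            raise ValueError("label array shape does not match dims")

    def point_coords(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Cartesian coordinates of all grid points (or those selected by mask)."""
        idx = np.indices(self.dims).reshape(3, -1).T if mask is None \
            else np.argwhere(mask)
        return self.origin + idx * self.spacing

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    @property
    def deep_volume(self) -> float:
        return self.count(DEEP_POCKET) * self.spacing ** 3

    @property
    def pocket_volume(self) -> float:
        return (self.count(POCKET) + self.count(DEEP_POCKET)) * self.spacing ** 3


@dataclass
class PocketCluster:
    member_points: np.ndarray    # (m, 3) integer grid indices
    deep_points: np.ndarray      # (k, 3) subset with deep label
    spacing: float
    contacts_target: bool = True
    bounding_box: tuple = field(default=None)

    @property
    def pocket_volume(self) -> float:
        return len(self.member_points) * self.spacing ** 3

    @property
    def deep_volume(self) -> float:
        return len(self.deep_points) * self.spacing ** 3


def _target_positions(structure: Structure, target_residues) -> np.ndarray:
    pos = []
    for chain, resnum in target_residues:
        try:
            atoms = structure.residue_atoms(chain, resnum)
        except KeyError as exc:
            raise KeyError(f"target residue {chain}:{resnum} absent from structure") from exc
        pos.extend(a.position for a in atoms)
    return np.array(pos, dtype=float)


def build_grid(structure: Structure, target_residues, params: GridParams) -> PocketGrid:
    """Cubic grid of edge ``edge_length`` centered at the target residues'
    center of mass (unit atom masses), all points initialized as solvent."""
    targets = [(str(c), int(r)) for c, r in target_residues]
    if not 1 <= len(targets) <= 2:
        raise ValueError("need 1 or 2 target residues")
    pos = _target_positions(structure, targets)
    center = pos.mean(axis=0)
    n = int(round(params.edge_length / params.spacing)) + 1
    origin = center - (n - 1) / 2 * params.spacing
    labels = np.full((n, n, n), SOLVENT, dtype=np.int8)
    return PocketGrid(origin, params.spacing, (n, n, n), labels, targets)


def _classify_labels(origin: np.ndarray, spacing: float, dims: tuple[int, int, int],
                     positions: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Vectorized vdW-surface rasterization: returns a SOLVENT/PROTEIN
    label array.  Each atom stamps the lattice points within its radius."""
    labels = np.full(dims, SOLVENT, dtype=np.int8)
    dims_arr = np.array(dims)
    rel = (positions - origin) / spacing          # fractional grid coords
    r_grid = radii / spacing
    # cull atoms whose sphere cannot intersect the grid
    near = np.all((rel > -r_grid[:, None]) & (rel < dims_arr - 1 + r_grid[:, None]), axis=1)
    rel, r_grid = rel[near], r_grid[near]
    if len(rel) == 0:
        return labels
    h = int(np.ceil(r_grid.max() + 0.5))  # rounded-center offset bound
    off = np.indices((2 * h + 1,) * 3).reshape(3, -1).T - h   # (m, 3)
    base = np.round(rel).astype(int)                          # (n, 3)
    cand = base[:, None, :] + off[None, :, :]                 # (n, m, 3)
    d2 = np.sum((cand - rel[:, None, :]) ** 2, axis=2)
    ok = (d2 <= (r_grid ** 2)[:, None]) & np.all(cand >= 0, axis=2) \
        & np.all(cand < dims_arr, axis=2)
    hits = cand[ok]
    labels[hits[:, 0], hits[:, 1], hits[:, 2]] = PROTEIN
    return labels


def classify_grid(grid: PocketGrid, structure: Structure) -> PocketGrid:
    """Map the protein vdW surface onto the grid: points within an atom's
    vdW radius of its center become protein, the rest stay solvent."""
    grid.labels = _classify_labels(grid.origin, grid.spacing, grid.dims,
                                   structure.positions(), structure.radii())
    return grid


def _shift(arr: np.ndarray, d: tuple[int, int, int], fill: bool) -> np.ndarray:
    """Shift a boolean array by lattice vector d, padding with `fill`."""
    out = np.full_like(arr, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(d):
        if s > 0:
            src[ax], dst[ax] = slice(0, arr.shape[ax] - s), slice(s, None)
        elif s < 0:
            src[ax], dst[ax] = slice(-s, None), slice(0, arr.shape[ax] + s)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _has_protein_along(protein: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """For each point: is there any protein point strictly behind it along -d?

    Computed by iterated propagation B <- shift(B | protein); the number of
    iterations equals the longest line length.
    """
    steps = max(protein.shape)
    # logarithmic doubling: after k rounds `acc` holds the union of
    # shift(protein, t*d) for t = 1 .. 2^k
    acc = _shift(protein, d, False)
    offset = 1
    while offset < steps:
        acc |= _shift(acc, tuple(c * offset for c in d), False)
        offset *= 2
    return acc


def _mark_labels(labels: np.ndarray, params: GridParams) -> np.ndarray:
    protein = labels == PROTEIN
    solvent = labels == SOLVENT
    bounded_count = np.zeros(labels.shape, dtype=np.int16)
    for d in params.scan_directions:
        fwd = _has_protein_along(protein, d)
        bwd = _has_protein_along(protein, tuple(-c for c in d))
        bounded_count += (fwd & bwd & solvent).astype(np.int16)
    out = labels.copy()
    out[solvent & (bounded_count >= params.min_bounded_directions)] = POCKET
    return out


def mark_pockets(grid: PocketGrid, params: GridParams) -> PocketGrid:
    """Mark solvent points lying on protein-bounded line segments as pocket.

    At this stage only protein/solvent labels exist, so a solvent point sits
    on a maximal solvent run bounded by protein at both ends iff some
    protein point lies on each side of it along the scan line.
    """
    grid.labels = _mark_labels(grid.labels, params)
    return grid


def _deep_labels(labels: np.ndarray, spacing: float, params: GridParams) -> np.ndarray:
    solvent = labels == SOLVENT
    pocket = labels == POCKET
    if not pocket.any():
        return labels
    if solvent.any():
        dist = ndimage.distance_transform_edt(~solvent, sampling=spacing)
    else:
        dist = np.full(labels.shape, np.inf)
    out = labels.copy()
    out[pocket & (dist > params.burial_distance)] = DEEP_POCKET
    return out


def compute_deep(grid: PocketGrid, params: GridParams) -> PocketGrid:
    """Relabel pocket points strictly more than ``burial_distance`` from every
    remaining solvent point as deep pocket (Euclidean point-center distance)."""
    grid.labels = _deep_labels(grid.labels, grid.spacing, params)
    return grid


def cluster_pockets(
    grid: PocketGrid, structure: Structure, params: GridParams | None = None
) -> list[PocketCluster]:
    """Connected components (26-neighbor) of pocket ∪ deep points, filtered
    by direct contact with the target residues.

    A cluster contacts the target iff any of its points lies within
    (atom vdW radius + contact_margin) of a target-residue atom center.
    Clusters are sorted by deep volume descending, ties by smallest member
    index lexicographically.
    """
    params = params or GridParams(spacing=grid.spacing)
    mask = (grid.labels == POCKET) | (grid.labels == DEEP_POCKET)
    if not mask.any():
        return []
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    target_atoms = []
    for chain, resnum in grid.target_residues:
        target_atoms.extend(structure.residue_atoms(chain, resnum))
    t_pos = np.array([a.position for a in target_atoms])
    t_rad = np.array([a.vdw_radius for a in target_atoms]) + params.contact_margin
    clusters: list[PocketCluster] = []
    for ci in range(1, n + 1):
        pts = np.argwhere(lab == ci)
        coords = grid.origin + pts * grid.spacing
        # contact test against every target atom with its own radius
        d = np.linalg.norm(coords[:, None, :] - t_pos[None, :, :], axis=2)
        if not np.any(d <= t_rad[None, :]):
            continue
        deep_mask = grid.labels[pts[:, 0], pts[:, 1], pts[:, 2]] == DEEP_POCKET
        clusters.append(
            PocketCluster(
                member_points=pts,
                deep_points=pts[deep_mask],
                spacing=grid.spacing,
                contacts_target=True,
                bounding_box=(tuple(pts.min(axis=0)), tuple(pts.max(axis=0))),
            )
        )
    clusters.sort(key=lambda c: (-c.deep_volume, tuple(map(tuple, c.member_points[:1]))))
    return clusters


def detect_pockets(
    structure: Structure,
    target_residues,
    params: GridParams | None = None,
) -> tuple[PocketGrid, list[PocketCluster], float]:
    """Full local pocket-detection pipeline.

    Returns the labeled grid, the retained (target-contacting) clusters, and
    the total deep volume in Å³ summed over retained clusters.
    """
    params = params or GridParams()
    grid = build_grid(structure, target_residues, params)
    classify_grid(grid, structure)
    mark_pockets(grid, params)
    compute_deep(grid, params)
    clusters = cluster_pockets(grid, structure, params)
    total_deep = float(sum(c.deep_volume for c in clusters))
    return grid, clusters, total_deep


def deep_volume_at(
    positions: np.ndarray,
    radii: np.ndarray,
    target_atom_indices: np.ndarray,
    params: GridParams,
) -> float:
    """Array-level deep-volume evaluation (no Structure objects).

    Same pipeline as :func:`detect_pockets` — grid centered at the target
    atoms' mean position, classify, mark, deep, cluster with the target
    contact filter — returning only the total retained deep volume.  This
    is the hot path the biased sampler evaluates at every Metropolis step.
    """
    t_pos = positions[target_atom_indices]
    center = t_pos.mean(axis=0)
    n = int(round(params.edge_length / params.spacing)) + 1
    origin = center - (n - 1) / 2 * params.spacing
    labels = _classify_labels(origin, params.spacing, (n, n, n), positions, radii)
    labels = _mark_labels(labels, params)
    labels = _deep_labels(labels, params.spacing, params)
    mask = (labels == POCKET) | (labels == DEEP_POCKET)
    if not mask.any():
        return 0.0
    lab, ncomp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    t_rad = radii[target_atom_indices] + params.contact_margin
    deep_total = 0
    for ci in range(1, ncomp + 1):
        pts = np.argwhere(lab == ci)
        coords = origin + pts * params.spacing
        d = np.linalg.norm(coords[:, None, :] - t_pos[None, :, :], axis=2)
        if np.any(d <= t_rad[None, :]):
            deep_total += int(np.count_nonzero(
                labels[pts[:, 0], pts[:, 1], pts[:, 2]] == DEEP_POCKET))
    return deep_total * params.spacing ** 3
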