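"""Exemplar construction: the "perfect ligand" pseudo-molecule of a pocket.

An exemplar complements a detected surface pocket: for every protein
hydrogen-bond donor (acceptor) whose ideal partner position falls inside
the pocket, a complementary acceptor (donor) probe is placed there; the
remaining deep-pocket volume is then filled greedily with hydrophobic
carbon-like atoms at a minimum center-center spacing of 1.7 Å.  Finally the
placed atoms are single-linkage clustered at 5 Å so that two small pockets
flanking the target residues merge into one exemplar, and the component
nearest the target residues is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .pocket_detection import (
    DEEP_POCKET,
    POCKET,
    SOLVENT,
    GridParams,
    PocketGrid,
    detect_pockets,
)
from .structure_io import (
    ACCEPTOR,
    DONOR,
    HYDROPHOBE,
    PolarGroup,
    Structure,
    TypedAtomSet,
    find_polar_groups,
)

logger = logging.getLogger(__name__)


@dataclass
class ExemplarParams:
    hbond_distance: float = 2.9     # Å, heavy atom -> probe along the H-bond direction
    min_spacing: float = 1.7        # Å, minimum center-center distance between exemplar atoms
    cluster_threshold: float = 5.0  # Å, single-linkage merge distance
    hydrophobe_radius: float = 1.70
    polar_radius: float = 1.50
    keep_all_components: bool = False


@dataclass
class Exemplar:
    atoms: TypedAtomSet
    source: str = ""
    deep_volume: float = 0.0

    def __len__(self) -> int:
        return len(self.atoms)


class NoPocketError(RuntimeError):
    pass


def _pocket_tree(grid: PocketGrid) -> cKDTree | None:
    mask = (grid.labels == POCKET) | (grid.labels == DEEP_POCKET)
    if not mask.any():
        return None
    return cKDTree(grid.point_coords(mask))


def place_polar_probes(
    structure: Structure,
    grid: PocketGrid,
    polar_groups: list[PolarGroup],
    params: ExemplarParams | None = None,
) -> TypedAtomSet:
    """Place complementary polar probes at ideal H-bond partner positions.

    A probe at ``heavy + hbond_distance * direction`` is retained iff it
    lies within one grid spacing of a pocket or deep-pocket point; a protein
    donor produces an acceptor probe and vice versa.
    """
    params = params or ExemplarParams()
    tree = _pocket_tree(grid)
    positions, feats = [], []
    if tree is not None:
        for g in polar_groups:
            complement = ACCEPTOR if g.kind == DONOR else DONOR
            for direction in g.directions:
                probe = g.heavy_atom.position + params.hbond_distance * direction
                d, _ = tree.query(probe)
                if d <= grid.spacing:
                    positions.append(probe)
                    feats.append(complement)
    if not positions:
        return TypedAtomSet(np.empty((0, 3)), [], np.empty(0), label="polar probes")
    radii = np.full(len(feats), params.polar_radius)
    return TypedAtomSet(np.array(positions), feats, radii, label="polar probes")


def fill_hydrophobic(
    grid: PocketGrid,
    placed: TypedAtomSet,
    params: ExemplarParams | None = None,
) -> TypedAtomSet:
    """Greedy hydrophobic fill of the deep-pocket volume.

    Candidate sites are deep grid points ordered by burial (distance to the
    nearest solvent point, descending; ties by lexicographic grid index); a
    site is accepted iff it keeps every pairwise center distance among
    exemplar atoms at least ``min_spacing``.
    """
    params = params or ExemplarParams()
    deep_mask = grid.labels == DEEP_POCKET
    if not deep_mask.any():
        return placed
    solvent = grid.labels == SOLVENT
    if solvent.any():
        burial = ndimage.distance_transform_edt(~solvent, sampling=grid.spacing)
    else:
        burial = np.full(grid.dims, np.inf)
    idx = np.argwhere(deep_mask)
    depth = burial[idx[:, 0], idx[:, 1], idx[:, 2]]
    # stable sort on lexicographic index, then stable sort by -depth
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
    idx, depth = idx[order], depth[order]
    order = np.argsort(-depth, kind="stable")
    sites = grid.origin + idx[order] * grid.spacing

    accepted: list[np.ndarray] = [p for p in placed.positions]
    new_sites: list[np.ndarray] = []
    min2 = params.min_spacing ** 2
    for s in sites:
        if accepted:
            arr = np.array(accepted)
            if np.min(np.sum((arr - s) ** 2, axis=1)) < min2:
                continue
        accepted.append(s)
        new_sites.append(s)
    if not new_sites:
        return placed
    positions = np.vstack([placed.positions, np.array(new_sites)]) \
        if len(placed) else np.array(new_sites)
    feats = list(placed.features) + [HYDROPHOBE] * len(new_sites)
    radii = np.concatenate([placed.radii, np.full(len(new_sites), params.hydrophobe_radius)])
    return TypedAtomSet(positions, feats, radii, label=placed.label or "exemplar")


def cluster_exemplar(
    atoms: TypedAtomSet,
    grid: PocketGrid,
    structure: Structure,
    params: ExemplarParams | None = None,
    deep_volume: float = 0.0,
    source: str = "",
) -> Exemplar:
    """Single-linkage clustering of exemplar atoms at the proximity threshold;
    the component whose centroid is nearest the target center of mass is kept
    (ties by larger atom count)."""
    params = params or ExemplarParams()
    if len(atoms) == 0:
        raise ValueError("cannot cluster an empty exemplar atom set")
    n = len(atoms)
    tree = cKDTree(atoms.positions)
    pairs = tree.query_pairs(params.cluster_threshold, output_type="ndarray")
    if len(pairs):
        data = np.ones(len(pairs))
        adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = csr_matrix((n, n))
    n_comp, comp = connected_components(adj, directed=False)
    if n_comp > 1 and not params.keep_all_components:
        t_pos = []
        for chain, resnum in grid.target_residues:
            t_pos.extend(a.position for a in structure.residue_atoms(chain, resnum))
        t_center = np.mean(np.array(t_pos), axis=0)
        best, best_key = None, None
        for c in range(n_comp):
            members = comp == c
            centroid = atoms.positions[members].mean(axis=0)
            key = (float(np.linalg.norm(centroid - t_center)), -int(members.sum()))
            if best_key is None or key < best_key:
                best, best_key = c, key
        keep = comp == best
        atoms = TypedAtomSet(
            atoms.positions[keep],
            [f for f, k in zip(atoms.features, keep) if k],
            atoms.radii[keep],
            label=atoms.label,
        )
    return Exemplar(atoms=atoms, source=source, deep_volume=deep_volume)


def build_exemplar(
    structure: Structure,
    target_residues,
    grid_params: GridParams | None = None,
    params: ExemplarParams | None = None,
    source: str = "",
) -> Exemplar:
    """Detect the pocket at the target residues and build its exemplar."""
    grid_params = grid_params or GridParams()
    params = params or ExemplarParams()
    grid, clusters, total_deep = detect_pockets(structure, target_residues, grid_params)
    if not clusters:
        raise NoPocketError("no pocket at target site")
    # restrict the grid to retained clusters so probes/fill stay in-contact
    keep = np.zeros(grid.dims, dtype=bool)
    for c in clusters:
        keep[c.member_points[:, 0], c.member_points[:, 1], c.member_points[:, 2]] = True
    labels = grid.labels.copy()
    stray = ((labels == POCKET) | (labels == DEEP_POCKET)) & ~keep
    labels[stray] = SOLVENT
    grid = PocketGrid(grid.origin, grid.spacing, grid.dims, labels, grid.target_residues)

    polar_groups = find_polar_groups(structure)
    placed = place_polar_probes(structure, grid, polar_groups, params)
    filled = fill_hydrophobic(grid, placed, params)
    if len(filled) == 0:
        raise NoPocketError("pocket has no deep volume and no polar probes")
    return cluster_exemplar(filled, grid, structure, params,
                            deep_volume=total_deep, source=source)


_FEATURE_TO_RES = {HYDROPHOBE: "HPH", DONOR: "DON", ACCEPTOR: "ACC"}
_RES_TO_FEATURE = {v: k for k, v in _FEATURE_TO_RES.items()}


def write_exemplar(exemplar: Exemplar) -> str:
    """Serialize an exemplar in a PDB-like record format.

    Feature is encoded in the residue-name column (HPH/DON/ACC); the atom
    radius rides in the B-factor column.  Positions keep 3 decimals.
    """
    if len(exemplar) == 0:
        raise ValueError("refusing to write an empty exemplar")
    lines = [f"REMARK EXEMPLAR source={exemplar.source} deep_volume={exemplar.deep_volume:.3f}"]
    for i in range(len(exemplar)):
        x, y, z = exemplar.atoms.positions[i]
        res = _FEATURE_TO_RES[exemplar.atoms.features[i]]
        r = exemplar.atoms.radii[i]
        lines.append(
            f"HETATM{i + 1:5d}  X   {res} X{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{r:6.2f}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_exemplar(text: str) -> Exemplar:
    """Parse the exemplar record format written by :func:`write_exemplar`."""
    source, deep_volume = "", 0.0
    positions, feats, radii = [], [], []
    for ln, line in enumerate(text.splitlines(), 1):
        if line.startswith("REMARK EXEMPLAR"):
            for tok in line.split():
                if tok.startswith("source="):
                    source = tok[len("source="):]
                elif tok.startswith("deep_volume="):
                    deep_volume = float(tok[len("deep_volume="):])
        elif line.startswith("HETATM"):
            try:
                res = line[17:20].strip()
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                r = float(line[60:66])
                feats.append(_RES_TO_FEATURE[res])
            except (ValueError, KeyError, IndexError) as exc:
                raise ValueError(f"malformed exemplar record at line {ln}: {line!r}") from exc
            positions.append((x, y, z))
            radii.append(r)
    if not positions:
        raise ValueError("no exemplar atoms found in input")
    atoms = TypedAtomSet(np.array(positions), feats, np.array(radii), label=source)
    return Exemplar(atoms=atoms, source=source, deep_volume=deep_volume)
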