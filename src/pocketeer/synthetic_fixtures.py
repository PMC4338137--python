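"""Deterministic pseudo-protein fixtures with known ground truth.

Real cryptic-pocket studies start from deposited crystal structures; these
generators instead build cup-shaped pseudo-proteins — thick spherical
shells of carbon-like atoms with pockets carved as cylinder or sphere
subtractions — plus polar wall decorations, matched protein families with
shared/distinct pockets, and toy per-residue ΔΔG tables.  Every in-scope
algorithm consumes only atoms, radii, residue identity and polar-group
geometry, so these fixtures exercise the full pipeline with generative
truth available for every stage.  All generators are pure functions of
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structure_io import Atom, Structure, assign_radii
from .target_selection import DdgTable

#: radial gap between lattice layers, Å; dense enough that no interstitial
#: void survives vdW coverage (the solid must read as convex on the grid)
LAYER_GAP = 1.7


@dataclass
class CarveOp:
    """Subtractive pocket: a cylinder drilled inward from the outer surface
    along ``direction``, or a sphere centered ``depth`` below the surface."""

    kind: str = "cylinder"          # cylinder | sphere
    direction: tuple = (0.0, 0.0, 1.0)
    radius: float = 3.0             # Å
    depth: float = 6.0              # Å, measured inward from the outer surface

    def axis(self) -> np.ndarray:
        u = np.asarray(self.direction, dtype=float)
        return u / np.linalg.norm(u)


@dataclass
class FixtureSpec:
    shell_radius: float = 9.0       # Å, outer layer radius
    n_atoms: int = 230              # atoms on the outer layer; inner layers scale by r²
    layer_gap: float = LAYER_GAP
    jitter: float = 0.03            # Å, symmetry-breaking positional noise
    carves: list = field(default_factory=list)
    polar_sites: list = field(default_factory=list)  # (CarveOp, "donor"|"acceptor")
    seed: int = 0


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on a sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    theta = phi * i
    return radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_shell_protein(spec: FixtureSpec) -> Structure:
    """Solid ball of carbon atoms built from concentric Fibonacci-lattice
    layers down to the center: convex, pocket-free, one single-atom residue
    per lattice site."""
    rng = np.random.default_rng(spec.seed)
    positions = [np.zeros((1, 3))]
    r = spec.shell_radius
    while r > spec.layer_gap / 2:
        n = max(int(round(spec.n_atoms * (r / spec.shell_radius) ** 2)), 12)
        positions.append(_fibonacci_sphere(n, r))
        r -= spec.layer_gap
    pos = np.vstack(positions)
    if len(pos) < 20:
        raise ValueError("fixture too small: fewer than 20 atoms")
    pos = pos + rng.normal(0.0, spec.jitter, pos.shape)
    atoms = [
        Atom(serial=i + 1, name="C", element="C", residue_name="ALA",
             chain="A", residue_number=i + 1, position=p)
        for i, p in enumerate(pos)
    ]
    st = Structure(atoms, id=f"shell_r{spec.shell_radius:g}_s{spec.seed}")
    return assign_radii(st)


def _in_carve(pos: np.ndarray, carve: CarveOp, outer_radius: float) -> np.ndarray:
    u = carve.axis()
    proj = pos @ u
    radial = np.linalg.norm(pos - np.outer(proj, u), axis=1)
    if carve.kind == "cylinder":
        return (radial < carve.radius) & (proj > outer_radius - carve.depth)
    if carve.kind == "sphere":
        center = u * (outer_radius - carve.depth)
        return np.linalg.norm(pos - center, axis=1) < carve.radius
    raise ValueError(f"unknown carve kind {carve.kind!r}")


def carve_pocket(structure: Structure, carve: CarveOp,
                 outer_radius: float | None = None) -> Structure:
    """Remove atoms inside the carve region, leaving a rimmed cavity."""
    pos = structure.positions()
    if outer_radius is None:
        outer_radius = float(np.linalg.norm(pos, axis=1).max())
    inside = _in_carve(pos, carve, outer_radius)
    if not inside.any():
        raise ValueError("carve region does not overlap the structure")
    if inside.sum() > 0.5 * len(structure):
        raise ValueError("carve would remove more than half of the atoms")
    atoms = [a for a, drop in zip(structure.atoms, inside) if not drop]
    return Structure(atoms, id=structure.id + "_carved")


def add_polar_site(structure: Structure, carve: CarveOp,
                   kind: str, outer_radius: float | None = None,
                   azimuth: float = 0.0) -> Structure:
    """Decorate the carve wall with a polar residue pointing into the cavity.

    ``kind='acceptor'`` plants a glycine-like carbonyl (C plus O aimed at
    the pocket axis → the exemplar gains a donor probe); ``kind='donor'``
    plants a serine-like hydroxyl (CB plus OG → donor+acceptor probes).
    """
    pos = structure.positions()
    if outer_radius is None:
        outer_radius = float(np.linalg.norm(pos, axis=1).max())
    u = carve.axis()
    # orthonormal frame around the carve axis
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    radial = np.cos(azimuth) * v + np.sin(azimuth) * w
    depth_point = u * (outer_radius - 0.5 * carve.depth)
    wall = depth_point + radial * (carve.radius + 0.4)
    inward = -radial
    next_serial = max(a.serial for a in structure.atoms) + 1
    next_res = max(a.residue_number for a in structure.atoms) + 1
    if kind == "acceptor":
        new = [
            Atom(next_serial, "C", "C", "GLY", "A", next_res, wall),
            Atom(next_serial + 1, "O", "O", "GLY", "A", next_res, wall + 1.23 * inward),
        ]
    elif kind == "donor":
        new = [
            Atom(next_serial, "CB", "C", "SER", "A", next_res, wall),
            Atom(next_serial + 1, "OG", "O", "SER", "A", next_res, wall + 1.41 * inward),
        ]
    else:
        raise ValueError("kind must be 'donor' or 'acceptor'")
    st = Structure(list(structure.atoms) + new, id=structure.id)
    return assign_radii(st)


def make_cup_protein(spec: FixtureSpec | None = None) -> Structure:
    """Shell with every carve and polar decoration of the spec applied."""
    spec = spec or FixtureSpec(carves=[CarveOp()])
    st = make_shell_protein(spec)
    outer = spec.shell_radius
    for carve in spec.carves:
        st = carve_pocket(st, carve, outer_radius=outer)
    for carve, kind in spec.polar_sites:
        st = add_polar_site(st, carve, kind, outer_radius=outer)
    return st


def rim_targets(structure: Structure, carve: CarveOp,
                outer_radius: float | None = None) -> list[tuple[str, int]]:
    """Two rim residues flanking the carve mouth, suitable as target
    residues: their center of mass sits over the pocket opening."""
    pos = structure.positions()
    if outer_radius is None:
        outer_radius = float(np.linalg.norm(pos, axis=1).max())
    u = carve.axis()
    proj = pos @ u
    radial = np.linalg.norm(pos - np.outer(proj, u), axis=1)
    # mouth ring: near the outer surface, just outside the carve radius
    score = np.abs(radial - (carve.radius + 1.2)) + np.abs(proj - (outer_radius - 1.0))
    first = int(np.argmin(score))
    rel = pos - proj[:, None] * u
    opposite = rel @ (-rel[first] / max(np.linalg.norm(rel[first]), 1e-9))
    score2 = score - 0.5 * opposite
    score2[first] = np.inf
    second = int(np.argmin(score2))
    return [
        (structure.atoms[first].chain, structure.atoms[first].residue_number),
        (structure.atoms[second].chain, structure.atoms[second].residue_number),
    ]


#: canonical carve geometries for the two family pockets
POCKET_A = CarveOp(kind="cylinder", direction=(0.0, 0.0, 1.0), radius=3.0, depth=6.0)
POCKET_B = CarveOp(kind="cylinder", direction=(1.0, 0.0, 0.0), radius=2.2, depth=7.5)


@dataclass
class FamilyFixture:
    structures: dict[str, Structure]
    targets: dict[str, list[tuple[str, int]]]
    pockets: dict[str, CarveOp]
    truth: pd.DataFrame  # rows: reference pocket id; columns: protein id; bool


def make_family(
    n_proteins: int = 3,
    shared_pocket: CarveOp = POCKET_A,
    distinct_pocket: CarveOp = POCKET_B,
    distinct_member: int = 2,           # 0-based index of the protein with pocket B
    distinct_mode: str = "instead",     # "instead" | "additionally"
    spec: FixtureSpec | None = None,
    seed: int = 0,
) -> FamilyFixture:
    """Family of shell proteins with a shared pocket A and a distinct pocket
    B carried by one member only; returns structures, per-protein target
    residues, and the generative truth table of which reference pocket each
    protein can present."""
    if not 0 <= distinct_member < n_proteins:
        raise ValueError("distinct_member out of range")
    if distinct_mode not in ("instead", "additionally"):
        raise ValueError("distinct_mode must be 'instead' or 'additionally'")
    base = spec or FixtureSpec()
    structures, targets = {}, {}
    truth = pd.DataFrame(
        False,
        index=["A", "B"],
        columns=[f"p{i + 1}" for i in range(n_proteins)],
        dtype=bool,
    )
    for i in range(n_proteins):
        pid = f"p{i + 1}"
        carves, polar = [], []
        if i != distinct_member or distinct_mode == "additionally":
            carves.append(shared_pocket)
            polar.append((shared_pocket, "acceptor"))
            truth.loc["A", pid] = True
        if i == distinct_member:
            carves.append(distinct_pocket)
            polar.append((distinct_pocket, "donor"))
            truth.loc["B", pid] = True
        s = replace(base, carves=carves, polar_sites=polar, seed=seed + 31 * i)
        st = make_cup_protein(s)
        st.id = pid
        structures[pid] = st
        anchor = distinct_pocket if (i == distinct_member and distinct_mode == "instead") \
            else shared_pocket
        targets[pid] = rim_targets(st, anchor, outer_radius=base.shell_radius)
    return FamilyFixture(structures, targets,
                         {"A": shared_pocket, "B": distinct_pocket}, truth)


def make_ddg_table(
    structure: Structure,
    hotspots: dict[tuple[str, int], float],
    n_background: int = 10,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> DdgTable:
    """Toy alanine-scan table: specified ΔΔG at the hotspot residues plus
    small seeded noise values on randomly drawn background residues."""
    rng = np.random.default_rng(seed)
    entries: dict[tuple[str, int], float] = {}
    all_residues = structure.residue_ids()
    for rid, value in hotspots.items():
        if rid not in structure.residue_index:
            raise KeyError(f"hotspot residue {rid} not in structure")
        entries[rid] = float(value)
    pool = [r for r in all_residues if r not in entries]
    take = min(n_background, len(pool))
    idx = rng.choice(len(pool), size=take, replace=False)
    for k in idx:
        entries[pool[k]] = float(abs(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 0.0
    return DdgTable(entries)


def make_toy_ligand(kind: str = "mixed", seed: int = 0):
    """Small bond-free typed atom sets standing in for ligand conformers."""
    from .structure_io import ACCEPTOR, DONOR, HYDROPHOBE, TypedAtomSet

    rng = np.random.default_rng(seed)
    if kind == "mixed":
        positions = np.array([
            [0.0, 0.0, 0.0], [1.8, 0.0, 0.0], [3.4, 0.8, 0.0],
            [1.0, 1.6, 0.5], [-1.2, 0.9, -0.4],
        ])
        feats = [HYDROPHOBE, HYDROPHOBE, HYDROPHOBE, DONOR, ACCEPTOR]
        radii = np.array([1.70, 1.70, 1.70, 1.50, 1.50])
    elif kind == "apolar":
        positions = _fibonacci_sphere(6, 1.9)
        feats = [HYDROPHOBE] * 6
        radii = np.full(6, 1.70)
    elif kind == "random":
        n = int(rng.integers(4, 9))
        positions = rng.uniform(-3, 3, (n, 3))
        feats = [str(rng.choice([HYDROPHOBE, DONOR, ACCEPTOR])) for _ in range(n)]
        radii = rng.uniform(1.3, 1.9, n)
    else:
        raise ValueError(f"unknown ligand kind {kind!r}")
    return TypedAtomSet(positions, feats, radii, label=f"ligand_{kind}_{seed}")
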