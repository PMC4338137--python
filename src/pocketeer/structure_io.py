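"""Protein and ligand structure I/O, van der Waals radii, and polar-group typing.

Structures are parsed from PDB text with :mod:`gemmi` into a light in-memory
``Structure`` (a flat atom table plus a residue index), which is all the
downstream grid and exemplar machinery needs.  Ligands come in as
``TypedAtomSet`` objects — bond-free typed atoms (donor / acceptor /
hydrophobe) — the same representation used for pocket exemplars, so ligands
and pockets can be compared directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Conventional van der Waals radii in Å (Bondi-like); the default covers
#: elements absent from the table.
DEFAULT_RADIUS_TABLE: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.09,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
DEFAULT_RADIUS: float = 1.80

HYDROPHOBE = "hydrophobe"
DONOR = "donor"
ACCEPTOR = "acceptor"
FEATURES = (HYDROPHOBE, DONOR, ACCEPTOR)

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    chain: str
    residue_number: int
    position: np.ndarray  # (3,) Å
    vdw_radius: float = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be positive")


@dataclass
class Structure:
    """Ordered atom list plus an index from (chain, residue_number) to atoms."""

    atoms: list[Atom] = field(default_factory=list)
    id: str = ""

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            self._index.setdefault((a.chain, a.residue_number), []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def residue_index(self) -> dict[tuple[str, int], list[int]]:
        return self._index

    def residue_ids(self) -> list[tuple[str, int]]:
        return list(self._index)

    def residue_atoms(self, chain: str, residue_number: int) -> list[Atom]:
        key = (chain, int(residue_number))
        if key not in self._index:
            raise KeyError(f"residue {chain}:{residue_number} not in structure")
        return [self.atoms[i] for i in self._index[key]]

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def with_positions(self, pos: np.ndarray, id: str | None = None) -> "Structure":
        """Copy of this structure with new coordinates (same atom ordering)."""
        pos = np.asarray(pos, dtype=float)
        if pos.shape != (len(self.atoms), 3):
            raise ValueError("position array shape mismatch")
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_name, a.chain,
                 a.residue_number, pos[i].copy(), a.vdw_radius)
            for i, a in enumerate(self.atoms)
        ]
        return Structure(atoms, id=self.id if id is None else id)


@dataclass
class PolarGroup:
    """A protein hydrogen-bond donor or acceptor heavy atom with idealized
    H-bond directions (unit vectors pointing away from the protein)."""

    heavy_atom: Atom
    kind: str  # "donor" | "acceptor"
    directions: list[np.ndarray]

    def __post_init__(self) -> None:
        if self.kind not in (DONOR, ACCEPTOR):
            raise ValueError(f"kind must be donor or acceptor, got {self.kind!r}")
        self.directions = [np.asarray(d, dtype=float) for d in self.directions]
        for d in self.directions:
            n = float(np.linalg.norm(d))
            if abs(n - 1.0) > 1e-6:
                raise ValueError("polar group direction is not unit-norm")


@dataclass
class TypedAtomSet:
    """Bond-free pseudo-molecule: positions, pharmacophore features, radii.

    Shared representation for pocket exemplars and ligand conformers.  An
    atom carrying both donor and acceptor character appears once per feature
    (two entries at the same position), which is how the Gaussian color
    overlap wants it.
    """

    positions: np.ndarray  # (n, 3) Å
    features: list[str]
    radii: np.ndarray  # (n,) Å
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        n = len(self.features)
        if self.positions.shape != (n, 3) or self.radii.shape != (n,):
            raise ValueError("positions/features/radii length mismatch")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        for f in self.features:
            if f not in FEATURES:
                raise ValueError(f"unknown feature {f!r}")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TypedAtomSet":
        pos = self.positions @ np.asarray(rotation, dtype=float).T + np.asarray(translation, dtype=float)
        return TypedAtomSet(pos, list(self.features), self.radii.copy(), self.label)


class ParseError(ValueError):
    pass


def read_structure(pdb_text: str, id: str = "") -> Structure:
    """Parse PDB-format text into a Structure.

    Waters are dropped; for alternate locations only blank or 'A' is kept.
    Raises ParseError on malformed records and on structures with no atoms.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"PDB parse failure: {exc}") from exc
    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for res in chain:
                if res.name.strip() in _WATER_NAMES:
                    continue
                for at in res:
                    if at.altloc not in ("", "\x00", "A"):
                        continue
                    atoms.append(
                        Atom(
                            serial=at.serial,
                            name=at.name.strip(),
                            element=at.element.name.upper(),
                            residue_name=res.name.strip(),
                            chain=chain.name.strip(),
                            residue_number=res.seqid.num,
                            position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        )
                    )
        break  # first model only
    if not atoms:
        raise ParseError("empty structure")
    return Structure(atoms, id=id)


def write_structure(structure: Structure) -> str:
    """Serialize a Structure back to PDB text (3-decimal coordinates)."""
    st = gemmi.Structure()
    st.name = structure.id or "pocketeer"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    current: dict[str, tuple[int, gemmi.Residue] | None] = {}
    for a in structure.atoms:
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chains[a.chain] = ch
            model.add_chain(ch)
            ch = model[a.chain]
            chains[a.chain] = ch
            current[a.chain] = None
        cur = current[a.chain]
        if cur is None or cur[0] != a.residue_number:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            ch.add_residue(res)
            res = ch[-1]
            current[a.chain] = (a.residue_number, res)
        else:
            res = cur[1]
        ga = gemmi.Atom()
        ga.name = a.name
        ga.element = gemmi.Element(a.element.capitalize())
        ga.pos = gemmi.Position(*a.position)
        ga.serial = a.serial
        res.add_atom(ga)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def assign_radii(
    structure: Structure,
    radius_table: dict[str, float] | None = None,
    default: float = DEFAULT_RADIUS,
) -> Structure:
    """Assign per-atom vdW radii from an element table (in place-ish: returns
    the same Structure with radii set).  Unknown elements get *default* and a
    logged warning."""
    table = {k.upper(): v for k, v in (radius_table or DEFAULT_RADIUS_TABLE).items()}
    unknown: set[str] = set()
    for a in structure.atoms:
        r = table.get(a.element.upper())
        if r is None:
            unknown.add(a.element)
            r = default
        a.vdw_radius = r
    for el in sorted(unknown):
        logger.warning("element %s not in radius table; using default %.2f Å", el, default)
    return structure


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-9:
        raise ValueError("zero-length direction")
    return v / n


# Side-chain polar groups: residue -> {atom: (kind(s), anchor atom for the
# bond direction)}.  Directions are idealized along the anchor->polar bond,
# extended outward; acceptor lone pairs collapse to that single direction.
_SIDECHAIN_POLAR: dict[str, list[tuple[str, str, str]]] = {
    "SER": [("OG", "both", "CB")],
    "THR": [("OG1", "both", "CB")],
    "TYR": [("OH", "both", "CZ")],
    "LYS": [("NZ", DONOR, "CE")],
    "ARG": [("NH1", DONOR, "CZ"), ("NH2", DONOR, "CZ"), ("NE", DONOR, "CD")],
    "ASP": [("OD1", ACCEPTOR, "CG"), ("OD2", ACCEPTOR, "CG")],
    "GLU": [("OE1", ACCEPTOR, "CD"), ("OE2", ACCEPTOR, "CD")],
    "ASN": [("OD1", ACCEPTOR, "CG"), ("ND2", DONOR, "CG")],
    "GLN": [("OE1", ACCEPTOR, "CD"), ("NE2", DONOR, "CD")],
    "HIS": [("ND1", "both", "CG"), ("NE2", "both", "CD2")],
    "TRP": [("NE1", DONOR, "CD1")],
}

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def find_polar_groups(structure: Structure) -> list[PolarGroup]:
    """Enumerate protein hydrogen-bond donors and acceptors with idealized
    H-bond partner directions.

    Backbone N (except proline) is a donor — the direction comes from an
    explicit amide H when present, otherwise from extending the CA→N bond.
    Backbone O is an acceptor along the C→O carbonyl direction.  Side-chain
    groups follow a fixed residue table.  Groups whose geometry cannot be
    built from the atoms present are skipped with a warning.
    """
    groups: list[PolarGroup] = []
    for (chain, resnum), idxs in structure.residue_index.items():
        res_atoms = [structure.atoms[i] for i in idxs]
        resname = res_atoms[0].residue_name
        if resname not in _STANDARD_RESIDUES:
            logger.warning("skipping non-standard residue %s %s:%d", resname, chain, resnum)
            continue
        by_name = {a.name: a for a in res_atoms}

        # backbone donor: amide N
        n_at = by_name.get("N")
        if n_at is not None and resname != "PRO":
            direction = None
            h_at = by_name.get("H") or by_name.get("HN") or by_name.get("H1")
            if h_at is not None:
                direction = h_at.position - n_at.position
            elif "CA" in by_name:
                direction = n_at.position - by_name["CA"].position
            if direction is not None and np.linalg.norm(direction) > 1e-6:
                groups.append(PolarGroup(n_at, DONOR, [_unit(direction)]))
            else:
                logger.warning("cannot orient backbone N of %s %s:%d", resname, chain, resnum)

        # backbone acceptor: carbonyl O
        o_at = by_name.get("O")
        if o_at is not None:
            c_at = by_name.get("C")
            if c_at is not None and np.linalg.norm(o_at.position - c_at.position) > 1e-6:
                groups.append(PolarGroup(o_at, ACCEPTOR, [_unit(o_at.position - c_at.position)]))
            else:
                logger.warning("cannot orient backbone O of %s %s:%d", resname, chain, resnum)

        for atom_name, kinds, anchor_name in _SIDECHAIN_POLAR.get(resname, []):
            p_at = by_name.get(atom_name)
            anchor = by_name.get(anchor_name)
            if p_at is None:
                continue
            if anchor is None or np.linalg.norm(p_at.position - anchor.position) < 1e-6:
                logger.warning(
                    "skipping %s of %s %s:%d (missing anchor %s)",
                    atom_name, resname, chain, resnum, anchor_name,
                )
                continue
            direction = _unit(p_at.position - anchor.position)
            for kind in ((DONOR, ACCEPTOR) if kinds == "both" else (kinds,)):
                groups.append(PolarGroup(p_at, kind, [direction]))
    return groups


def _type_heavy_atom(element: str, has_h: bool, n_bonds: int) -> list[str]:
    el = element.upper()
    if el in ("N", "O"):
        feats = []
        if has_h:
            feats.append(DONOR)
        # lone-pair heuristic: O always accepts; N accepts when not
        # valence-saturated (quaternary/amide-like counted by bond order sum)
        if el == "O" or n_bonds < 4:
            feats.append(ACCEPTOR)
        return feats or [ACCEPTOR]
    return [HYDROPHOBE]


def read_ligand(
    ligand_text: str,
    format: str = "sdf",
    radius_table: dict[str, float] | None = None,
    label: str = "",
) -> TypedAtomSet:
    """Read a small-molecule ligand and type its heavy atoms.

    Typing rule: N/O bearing an (explicit or implicit) hydrogen → donor;
    N/O with an available lone pair → acceptor (an atom may be both);
    C, S, P and halogens → hydrophobe.  Hydrogens themselves are dropped.
    """
    table = {k.upper(): v for k, v in (radius_table or DEFAULT_RADIUS_TABLE).items()}
    if format == "sdf":
        from rdkit import Chem

        mol = Chem.MolFromMolBlock(ligand_text, removeHs=False, sanitize=False)
        if mol is None:
            raise ParseError("unreadable SDF/mol block")
        try:
            Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES)
        except Exception:
            pass
        conf = mol.GetConformer()
        coords = conf.GetPositions()
        if not conf.Is3D() and np.allclose(coords[:, 2], 0.0):
            raise ParseError("ligand has 2D-only coordinates")
        positions, feats, radii = [], [], []
        for atom in mol.GetAtoms():
            el = atom.GetSymbol().upper()
            if el == "H":
                continue
            has_h = atom.GetTotalNumHs(includeNeighbors=True) > 0
            n_bonds = int(atom.GetTotalValence())
            for f in _type_heavy_atom(el, has_h, n_bonds):
                positions.append(coords[atom.GetIdx()])
                feats.append(f)
                radii.append(table.get(el, DEFAULT_RADIUS))
        if not positions:
            raise ParseError("ligand has no heavy atoms")
        return TypedAtomSet(np.array(positions), feats, np.array(radii), label=label)
    elif format == "pdb":
        st = read_structure(ligand_text, id=label)
        heavy = [a for a in st.atoms if a.element.upper() != "H"]
        hydro = [a for a in st.atoms if a.element.upper() == "H"]
        if np.allclose([a.position[2] for a in st.atoms], 0.0):
            raise ParseError("ligand has 2D-only coordinates")
        positions, feats, radii = [], [], []
        for a in heavy:
            has_h = any(np.linalg.norm(h.position - a.position) < 1.25 for h in hydro)
            n_bonds = sum(
                1 for b in heavy
                if b is not a and np.linalg.norm(b.position - a.position) < 1.8
            ) + (1 if has_h else 0)
            for f in _type_heavy_atom(a.element, has_h, n_bonds):
                positions.append(a.position)
                feats.append(f)
                radii.append(table.get(a.element.upper(), DEFAULT_RADIUS))
        return TypedAtomSet(np.array(positions), feats, np.array(radii), label=label)
    raise ValueError(f"unknown ligand format {format!r}")
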