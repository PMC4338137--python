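"""Target-residue selection from per-residue interface energetics.

Given a protein-protein complex and a table of per-residue binding
free-energy contributions (ΔΔGres, e.g. from computational alanine
scanning), every unordered pair of interfacial residues is tested by
centering a candidate cubic grid (default edge 24 Å) at the pair's center
of mass and summing ΔΔGres over the residues that fall on the grid.  The
pair capturing the largest cumulative ΔΔGres anchors the pocket grid; the
full ranking is returned because the second-best pair is sometimes useful
as an alternative anchor.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .structure_io import Structure

ResidueId = tuple[str, int]


@dataclass
class DdgTable:
    """Per-residue ΔΔG entries: (chain, residue_number) -> energy units."""

    entries: dict[ResidueId, float]

    def __post_init__(self) -> None:
        for rid, v in self.entries.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite ddG for residue {rid}")

    @classmethod
    def from_tsv(cls, text: str) -> "DdgTable":
        df = pd.read_csv(
            io.StringIO(text),
            sep="\t",
            comment="#",
            names=["chain", "resnum", "ddg"],
            dtype={"chain": str},
        )
        entries: dict[ResidueId, float] = {}
        for _, row in df.iterrows():
            rid = (str(row["chain"]), int(row["resnum"]))
            if rid in entries:
                raise ValueError(f"duplicate residue {rid} in ddG table")
            entries[rid] = float(row["ddg"])
        return cls(entries)

    def to_tsv(self) -> str:
        lines = [f"{c}\t{r}\t{v:.4f}" for (c, r), v in sorted(self.entries.items())]
        return "\n".join(lines) + "\n"


@dataclass
class TargetPairScore:
    pair: tuple[ResidueId, ResidueId]
    grid_center: np.ndarray
    captured_ddg: float
    rank: int = 0


def _pair_center(structure: Structure, pair) -> np.ndarray:
    pos = []
    for chain, resnum in pair:
        pos.extend(a.position for a in structure.residue_atoms(chain, resnum))
    arr = np.array(pos, dtype=float)
    if arr.size == 0:
        raise ValueError(f"pair {pair} has no atom coordinates")
    return arr.mean(axis=0)  # unit masses


def score_pair(
    structure: Structure,
    ddg: DdgTable,
    pair,
    edge_length: float = 24.0,
    clip_negative: bool = False,
) -> TargetPairScore:
    """Sum ΔΔGres over residues with any atom inside the candidate cube
    centered at the pair's (unit-mass) center of mass."""
    pair = tuple((str(c), int(r)) for c, r in pair)
    center = _pair_center(structure, pair)
    half = edge_length / 2.0
    captured = 0.0
    for rid, value in ddg.entries.items():
        try:
            atoms = structure.residue_atoms(*rid)
        except KeyError:
            continue
        pos = np.array([a.position for a in atoms])
        inside = np.all(np.abs(pos - center) <= half, axis=1)
        if inside.any():
            captured += max(value, 0.0) if clip_negative else value
    return TargetPairScore(pair=pair, grid_center=center, captured_ddg=captured)


def select_target_pair(
    structure: Structure,
    ddg: DdgTable,
    edge_length: float = 24.0,
    clip_negative: bool = False,
) -> list[TargetPairScore]:
    """Exhaustively score all unordered pairs of interfacial residues.

    Returns the full ranking by captured ΔΔG descending; ties break by the
    lexicographically smallest (chain, residue number) pair.
    """
    residues = sorted(ddg.entries)
    if len(residues) < 2:
        raise ValueError("need at least 2 interfacial residues in the ddG table")
    scores = [
        score_pair(structure, ddg, pair, edge_length, clip_negative)
        for pair in combinations(residues, 2)
    ]
    scores.sort(key=lambda s: (-s.captured_ddg, s.pair))
    for i, s in enumerate(scores):
        s.rank = i + 1
    return scores
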