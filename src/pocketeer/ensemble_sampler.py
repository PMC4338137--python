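"""Biased conformational sampling toward pocket-containing states.

Metropolis Monte Carlo on a stand-in all-atom energy (soft-sphere repulsion
plus an elastic network over reference contacts) augmented with the pocket
biasing term

    E' = E + c · V_deep,     c = −0.25 energy units / Å³ by default,

where V_deep is the deep pocket volume measured on a grid anchored at the
target residues.  Because c is negative, conformations exposing more deep
pocket volume are favored, driving the search toward cryptic-pocket-open
states.  Each ensemble member comes from an independent trajectory; output
conformations carry their energy re-evaluated *without* the bias, and the
ensemble can be filtered to conformations within an energy window (default
15 units) of an unbiased reference ensemble.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .exemplar import Exemplar
from .pocket_detection import GridParams, deep_volume_at, detect_pockets
from .structure_io import Structure

logger = logging.getLogger(__name__)


@dataclass
class EnergyParams:
    """Stand-in energy: quartic soft-sphere repulsion plus an elastic
    network over reference contacts within 10 Å.

    The repulsion onset for each pair is min(contact_distance, reference
    separation), so the reference conformation is exactly clash-free (E=0)
    even for densely packed pseudo-protein lattices, while any approach
    closer than the reference (or the generic 3.4 Å contact) is penalized.
    """

    contact_distance: float = 3.4   # Å, generic soft-sphere onset
    repulsion_k: float = 10.0       # units/Å⁴
    elastic_k: float = 0.05         # units/Å²
    elastic_cutoff: float = 10.0    # Å, reference contact cutoff


@dataclass
class SamplerConfig:
    bias_constant: float = -0.25      # energy units per Å³ of deep volume
    temperature: float = 1.0          # Metropolis scale (kT)
    steps: int = 2000                 # Metropolis steps per trajectory
    jitter_sigma: float = 0.3         # Å, per-atom Gaussian displacement
    group_rotation_prob: float = 0.2  # probability of a residue-rotation move
    group_rotation_sigma: float = 0.15  # rad
    seed: int = 0
    n_conformations: int = 1000
    energy_window: float = 15.0       # units, filter vs unbiased ensemble
    window_reference: str = "median"  # median | min | max
    energy: EnergyParams = field(default_factory=EnergyParams)
    grid: GridParams = field(default_factory=lambda: GridParams(edge_length=12.0, spacing=1.0))

    def __post_init__(self) -> None:
        if self.steps < 0 or self.jitter_sigma <= 0 or self.energy_window < 0:
            raise ValueError("invalid sampler configuration")

    def digest(self) -> str:
        h = hashlib.sha256(repr(self).encode()).hexdigest()
        return h[:12]


@dataclass
class Conformation:
    structure: Structure
    unbiased_energy: float
    deep_volume: float
    trajectory_id: int = 0
    seed: int = 0
    exemplar: Exemplar | None = None


@dataclass
class Ensemble:
    conformations: list[Conformation]
    start_id: str = ""
    target_residues: list = field(default_factory=list)
    config_digest: str = ""

    def __len__(self) -> int:
        return len(self.conformations)

    def energies(self) -> np.ndarray:
        return np.array([c.unbiased_energy for c in self.conformations])

    def deep_volumes(self) -> np.ndarray:
        return np.array([c.deep_volume for c in self.conformations])


class _EnergyModel:
    """Precomputed stand-in energy for a fixed reference structure."""

    def __init__(self, reference: Structure, params: EnergyParams):
        self.params = params
        self.ref_pos = reference.positions()
        self.n = len(self.ref_pos)
        d_ref_all = pdist(self.ref_pos)
        iu = np.triu_indices(self.n, k=1)
        contact = d_ref_all <= params.elastic_cutoff
        self.pairs_i = iu[0][contact]
        self.pairs_j = iu[1][contact]
        self.d_ref = d_ref_all[contact]
        # per-pair repulsion onset: never penalize the reference itself
        self.onset = np.minimum(params.contact_distance, d_ref_all)

    def __call__(self, pos: np.ndarray) -> float:
        if pos.shape != self.ref_pos.shape:
            raise ValueError("structure does not share atoms with the reference")
        p = self.params
        d_all = pdist(pos)
        gap = self.onset - d_all
        close = gap > 0
        rep = p.repulsion_k * np.sum(gap[close] ** 4) if close.any() else 0.0
        # elastic network on reference contacts
        d_pairs = np.linalg.norm(pos[self.pairs_i] - pos[self.pairs_j], axis=1)
        ela = p.elastic_k * np.sum((d_pairs - self.d_ref) ** 2)
        return float(rep + ela)


def stand_in_energy(structure: Structure, reference: Structure,
                    params: EnergyParams | None = None) -> float:
    """Soft-sphere + elastic-network energy of ``structure`` relative to the
    reference conformation.  Zero for the clash-free reference itself."""
    model = _EnergyModel(reference, params or EnergyParams())
    return model(structure.positions())


def biased_energy(structure: Structure, reference: Structure, target_residues,
                  config: SamplerConfig | None = None) -> tuple[float, float, float]:
    """(E_biased, E_unbiased, deep_volume) with E' = E + c·V_deep."""
    config = config or SamplerConfig()
    e_unbiased = stand_in_energy(structure, reference, config.energy)
    _, _, deep = detect_pockets(structure, target_residues, config.grid)
    return e_unbiased + config.bias_constant * deep, e_unbiased, deep


def _residue_groups(structure: Structure) -> list[np.ndarray]:
    return [np.array(idxs) for idxs in structure.residue_index.values()]


def _metropolis(start: Structure, target_residues, config: SamplerConfig,
                seed: int, record_interval: int | None = None):
    """Core Metropolis loop.  When the bias constant is zero the deep-volume
    term contributes nothing to the acceptance rule, so its (expensive)
    evaluation is deferred to the final conformation; the chain is identical
    either way.  Returns (positions, E_unbiased, deep_volume, samples)."""
    rng = np.random.default_rng(seed)
    model = _EnergyModel(start, config.energy)
    groups = _residue_groups(start)
    pos = start.positions().copy()
    radii = start.radii()
    target_idx = np.concatenate([
        start.residue_index[(str(c), int(r))] for c, r in target_residues
    ]).astype(int)
    biased = config.bias_constant != 0.0

    def deep_of(p):
        return deep_volume_at(p, radii, target_idx, config.grid)

    e_unb = model(pos)
    deep = deep_of(pos) if biased else None
    e_total = e_unb + config.bias_constant * deep if biased else e_unb
    accepted = 0
    samples: list[np.ndarray] = []
    for step in range(config.steps):
        trial = pos.copy()
        if rng.random() < config.group_rotation_prob and groups:
            g = groups[rng.integers(len(groups))]
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.normal(0.0, config.group_rotation_sigma)
            c, s = np.cos(angle), np.sin(angle)
            kx = np.array([[0, -axis[2], axis[1]],
                           [axis[2], 0, -axis[0]],
                           [-axis[1], axis[0], 0]])
            rot = np.eye(3) + s * kx + (1 - c) * (kx @ kx)
            center = trial[g].mean(axis=0)
            trial[g] = (trial[g] - center) @ rot.T + center
        else:
            i = rng.integers(len(pos))
            trial[i] = trial[i] + rng.normal(0.0, config.jitter_sigma, 3)
        e_trial_unb = model(trial)
        if biased:
            deep_trial = deep_of(trial)
            e_trial = e_trial_unb + config.bias_constant * deep_trial
        else:
            deep_trial, e_trial = None, e_trial_unb
        delta = e_trial - e_total
        if delta <= 0 or rng.random() < np.exp(-delta / config.temperature):
            pos, e_total, e_unb, deep = trial, e_trial, e_trial_unb, deep_trial
            accepted += 1
        if record_interval and (step + 1) % record_interval == 0:
            samples.append(pos.copy())
    if config.steps > 0 and accepted == 0:
        logger.warning("trajectory seed=%d accepted no moves", seed)
    if deep is None:
        deep = deep_of(pos)
    return pos, e_unb, deep, samples


def run_trajectory(start: Structure, target_residues,
                   config: SamplerConfig, seed: int | None = None) -> Conformation:
    """One independent Metropolis trajectory; returns the final accepted
    conformation with its bias-free energy.  Fully reproducible from seed."""
    seed = config.seed if seed is None else seed
    pos, e_unb, deep, _ = _metropolis(start, target_residues, config, seed)
    final = start.with_positions(pos)
    # bookkeeping invariant: E_biased − E_unbiased = c·V_deep by construction
    return Conformation(structure=final, unbiased_energy=e_unb, deep_volume=deep, seed=seed)


def trajectory_samples(start: Structure, target_residues, config: SamplerConfig,
                       seed: int | None = None, record_interval: int = 10,
                       burn_in: int = 0) -> list[np.ndarray]:
    """Position snapshots along one chain (for sampling-correctness checks),
    recorded every ``record_interval`` steps after ``burn_in`` steps."""
    seed = config.seed if seed is None else seed
    _, _, _, samples = _metropolis(start, target_residues, config, seed,
                                   record_interval=record_interval)
    skip = burn_in // max(record_interval, 1)
    return samples[skip:]


def generate_ensemble(start: Structure, target_residues,
                      config: SamplerConfig | None = None,
                      n_conformations: int | None = None) -> Ensemble:
    """n independent trajectories with per-trajectory seeds base_seed + index."""
    config = config or SamplerConfig()
    n = config.n_conformations if n_conformations is None else n_conformations
    confs = []
    for i in range(n):
        c = run_trajectory(start, target_residues, config, seed=config.seed + i)
        c.trajectory_id = i
        confs.append(c)
    return Ensemble(confs, start_id=start.id, target_residues=list(target_residues),
                    config_digest=config.digest())


def merge_ensembles(*ensembles: Ensemble) -> Ensemble:
    """Combine ensembles (e.g. from multiple target pairs) into one; the
    members keep their provenance."""
    confs = [c for e in ensembles for c in e.conformations]
    ids = sorted({e.start_id for e in ensembles})
    return Ensemble(confs, start_id="+".join(ids),
                    target_residues=[t for e in ensembles for t in [e.target_residues]],
                    config_digest=";".join(e.config_digest for e in ensembles))


def filter_by_energy(biased: Ensemble, unbiased: Ensemble,
                     window: float = 15.0, reference: str = "median") -> Ensemble:
    """Keep biased-ensemble conformations whose bias-free energy lies within
    ``window`` units of the unbiased ensemble's reference statistic."""
    if len(unbiased) == 0:
        raise ValueError("unbiased reference ensemble is empty")
    stat = {"median": np.median, "min": np.min, "max": np.max}[reference]
    cutoff = float(stat(unbiased.energies())) + window
    kept = [c for c in biased.conformations if c.unbiased_energy <= cutoff]
    return Ensemble(kept, start_id=biased.start_id,
                    target_residues=biased.target_residues,
                    config_digest=biased.config_digest)
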