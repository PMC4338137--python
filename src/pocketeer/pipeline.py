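"""End-to-end orchestration: structures → ensembles → exemplars → selectivity.

`run_pipeline` wires every stage together the way a family-selectivity
study uses them: generate (or load) a protein family, sample a biased and
an unbiased ensemble per member, energy-filter the biased ensembles, build
per-conformation exemplars, then produce the distance matrix, MDS map,
distinctness values, selectivity Z-score rows against reference pockets,
and a ROC summary against known labels.  All outputs are deterministic
functions of the resolved configuration (written alongside the results).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .ensemble_sampler import (
    EnergyParams,
    SamplerConfig,
    filter_by_energy,
    generate_ensemble,
)
from .exemplar import NoPocketError, build_exemplar, write_exemplar
from .pocket_detection import GridParams
from .selectivity_analysis import (
    classical_mds,
    distance_matrix,
    distinctness,
    roc_evaluate,
    selectivity_row,
)
from .shape_align import AlignConfig
from .synthetic_fixtures import make_family

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed", "out_dir", "preset", "n_conformations", "n_unbiased", "steps",
    "bias_constant", "energy_window", "distinctness_subsample",
    "sampler_grid_edge", "sampler_grid_spacing",
    "exemplar_grid_edge", "exemplar_grid_spacing",
    "align_random_starts", "align_max_evals", "elastic_k", "write_conformations",
}


@dataclass
class RunConfig:
    """Resolved pipeline configuration (flat keys; nested objects derived)."""

    seed: int = 0
    out_dir: str = "pocketeer_run"
    preset: str = "family3"
    n_conformations: int = 50
    n_unbiased: int = 10
    steps: int = 200
    bias_constant: float = -0.25
    energy_window: float = 15.0
    distinctness_subsample: int = 6
    sampler_grid_edge: float = 12.0
    sampler_grid_spacing: float = 1.0
    exemplar_grid_edge: float = 12.0
    exemplar_grid_spacing: float = 0.7
    align_random_starts: int = 2
    align_max_evals: int = 150
    elastic_k: float = 0.05
    write_conformations: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    def sampler_config(self, bias: float | None = None) -> SamplerConfig:
        return SamplerConfig(
            bias_constant=self.bias_constant if bias is None else bias,
            steps=self.steps,
            seed=self.seed,
            n_conformations=self.n_conformations,
            energy_window=self.energy_window,
            energy=EnergyParams(elastic_k=self.elastic_k),
            grid=GridParams(self.sampler_grid_edge, self.sampler_grid_spacing),
        )

    def exemplar_grid(self) -> GridParams:
        return GridParams(self.exemplar_grid_edge, self.exemplar_grid_spacing)

    def align_config(self) -> AlignConfig:
        return AlignConfig(n_random_starts=self.align_random_starts,
                           max_evals=self.align_max_evals)


@dataclass
class PipelineResult:
    config: RunConfig
    ensembles: dict
    exemplars: dict            # protein id -> list of Exemplar
    references: dict           # reference id -> Exemplar
    truth: pd.DataFrame | None
    rows: list
    auc: float | None
    roc_p: float | None
    distance_labels: list
    distances: object          # DistanceMatrix over the distinctness subsample
    mds: pd.DataFrame
    distinctness_values: list
    timings: dict


def _stage(timings: dict, name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.time()
            logger.info("stage %s ...", name)
            return self

        def __exit__(self, *exc):
            timings[name] = round(time.time() - self.t0, 2)
            logger.info("stage %s done in %.1fs", name, timings[name])
    return _T()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the family-selectivity workflow for the configured preset.

    Currently ships the ``family3`` preset (three pseudo-proteins, shared
    pocket A in members 1–2, distinct pocket B in member 3); external-input
    runs reuse the same stage functions through the library API.
    """
    timings: dict[str, float] = {}
    if config.preset != "family3":
        raise ValueError(f"unknown preset {config.preset!r}")

    with _stage(timings, "fixtures"):
        fam = make_family(seed=config.seed)

    ex_grid = config.exemplar_grid()
    with _stage(timings, "ensembles"):
        ensembles, exemplars = {}, {}
        for k, (pid, st) in enumerate(fam.structures.items()):
            cfg = config.sampler_config()
            cfg = dataclasses.replace(cfg, seed=config.seed + 1000 * (k + 1))
            biased = generate_ensemble(st, fam.targets[pid], cfg,
                                       n_conformations=config.n_conformations)
            ucfg = dataclasses.replace(cfg, bias_constant=0.0,
                                       seed=cfg.seed + 500_000)
            unbiased = generate_ensemble(st, fam.targets[pid], ucfg,
                                         n_conformations=config.n_unbiased)
            kept = filter_by_energy(biased, unbiased, window=config.energy_window)
            logger.info("%s: %d/%d conformations within the %.0f-unit window",
                        pid, len(kept), len(biased), config.energy_window)
            ensembles[pid] = kept

    with _stage(timings, "exemplars"):
        for pid, ens in ensembles.items():
            exs = []
            for c in ens.conformations:
                try:
                    ex = build_exemplar(c.structure, fam.targets[pid], ex_grid,
                                        source=f"{pid}/{c.trajectory_id}")
                except NoPocketError:
                    logger.info("%s conformation %d: no pocket", pid, c.trajectory_id)
                    continue
                c.exemplar = ex
                exs.append(ex)
            if not exs:
                raise RuntimeError(f"no exemplars for protein {pid}")
            exemplars[pid] = exs

    with _stage(timings, "references"):
        # reference pockets: built from the start structures of the members
        # that carry each pocket (the inhibitor-bound-pocket stand-ins)
        references = {}
        for ref_id in fam.truth.index:
            carrier = fam.truth.columns[fam.truth.loc[ref_id]][0]
            references[ref_id] = build_exemplar(
                fam.structures[carrier], fam.targets[carrier], ex_grid,
                source=f"ref{ref_id}/{carrier}")

    ac = config.align_config()
    with _stage(timings, "selectivity"):
        rows = []
        for ref_id, ref in references.items():
            labels = {pid: ("strong" if fam.truth.loc[ref_id, pid] else "none")
                      for pid in exemplars}
            rows.append(selectivity_row(ref, exemplars, reference_id=ref_id,
                                        labels=labels, config=ac))
        auc, roc_p, _ = roc_evaluate(rows)

    with _stage(timings, "distinctness"):
        flat, labels, membership = [], [], {}
        for pid, exs in exemplars.items():
            take = exs[:config.distinctness_subsample]
            membership[pid] = list(range(len(flat), len(flat) + len(take)))
            flat.extend(take)
            labels.extend(f"{pid}_{i}" for i in range(len(take)))
        dm = distance_matrix(flat, labels, config=ac)
        dvals = distinctness(membership, dm)
        mds = classical_mds(dm, dim=2)

    return PipelineResult(
        config=config, ensembles=ensembles, exemplars=exemplars,
        references=references, truth=fam.truth, rows=rows, auc=auc,
        roc_p=roc_p, distance_labels=labels, distances=dm, mds=mds,
        distinctness_values=dvals, timings=timings,
    )


def write_report(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write the deterministic report bundle for a pipeline run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    digest = cfg.digest()
    (out / "resolved_config.json").write_text(
        json.dumps({"config_hash": digest, **cfg.to_dict()}, indent=2) + "\n")

    result.distances.to_frame().to_csv(out / "distance_matrix.tsv", sep="\t")
    result.mds.to_csv(out / "mds_coordinates.tsv", sep="\t")

    pd.DataFrame(
        [{"protein": v.protein_id, "conformation": v.conformation_id,
          "d_other": v.d_other, "d_self": v.d_self,
          "distinctness": v.distinctness}
         for v in result.distinctness_values]
    ).to_csv(out / "distinctness.tsv", sep="\t", index=False)

    sel = pd.DataFrame(
        {row.reference_id: dict(zip(row.protein_ids, row.z_scores))
         for row in result.rows}).T
    sel.to_csv(out / "selectivity_zscores.tsv", sep="\t")

    (out / "roc_summary.json").write_text(json.dumps({
        "config_hash": digest,
        "auc": result.auc,
        "mann_whitney_p": result.roc_p,
        "n_rows": len(result.rows),
    }, indent=2) + "\n")

    exdir = out / "exemplars"
    exdir.mkdir(exist_ok=True)
    for ref_id, ex in result.references.items():
        (exdir / f"reference_{ref_id}.pdb").write_text(write_exemplar(ex))
    (out / "timings.json").write_text(json.dumps(result.timings, indent=2) + "\n")
    return out
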