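"""Orchestration: simulate -> preprocess -> connectivity -> inference -> report.

A run is fully determined by its configuration and top-level RNG seed;
re-running with the report's config echo reproduces the report
bit-identically. Each stage flushes its outputs before the next begins, so
partial results survive a failing stage.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as plio
from .clinical import comparison_frame, summarize
from .config import RunConfig
from .connectivity import plv_matrix, rsn_fc, seed_fc_from_analytic
from .inference import (
    CBPTConfig,
    cluster_permutation_test,
    restrict_adjacency,
    rsn_group_test,
)
from .preprocessing import BandSpec, analytic_epochs
from .simulate import (
    CohortSpec,
    EffectSpec,
    simulate_clinical,
    simulate_cohort,
)
from .source_space import (
    SeedROI,
    SourceGrid,
    build_adjacency,
    build_regular_grid,
    build_rsn,
    default_rsn_coordinates,
    load_roi_definitions,
)

logger = logging.getLogger(__name__)

__all__ = ["StageError", "RunReport", "run_pipeline"]

GROUP_ORDER = ("robust", "frail")  # positive t = robust > frail


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    """Everything a run produced, traceable to config + seed."""

    config: dict
    seed_results: dict = field(default_factory=dict)
    rsn_results: dict = field(default_factory=dict)
    clinical_rows: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    timings: dict = field(default_factory=dict)
    version: str = ""

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed_results": self.seed_results,
            "rsn_results": self.rsn_results,
            "clinical": self.clinical_rows,
            "warnings": self.warnings,
            "timings_s": {k: round(v, 3) for k, v in self.timings.items()},
            "version": self.version,
            "note": (
                "seed/band/laterality analyses are tested separately without "
                "cross-analysis correction; RSN tests are uncorrected across "
                "networks and bands"
            ),
        }


def _build_cohort(cfg: RunConfig):
    """Return (grid, subjects: list of (subject_id, group, data), fs)."""
    if cfg.simulate is not None:
        sim = cfg.simulate
        box = tuple((0.0, sim.grid_spacing * (s - 1)) for s in sim.grid_shape)
        grid = build_regular_grid(box, sim.grid_spacing)
        effect = None
        if not sim.null_cohort and sim.effect_seed_indices and sim.effect_target_indices:
            effect = EffectSpec(
                seed=SeedROI(
                    name="effect_seed",
                    laterality="bilateral",
                    source_indices=np.asarray(sim.effect_seed_indices),
                ),
                target_indices=np.asarray(sim.effect_target_indices),
                band=sim.effect_band,
                rho_robust=sim.effect_rho_robust,
                delta_rho=sim.effect_delta_rho,
            )
        spec = CohortSpec(
            n_robust=sim.n_robust,
            n_frail=sim.n_frail,
            grid=grid,
            epochs_mean_robust=sim.epochs_mean_robust,
            epochs_sd_robust=sim.epochs_sd_robust,
            epochs_mean_frail=sim.epochs_mean_frail,
            epochs_sd_frail=sim.epochs_sd_frail,
            min_epochs=sim.min_epochs,
            bands=tuple(BandSpec(b.name, b.lo, b.hi) for b in cfg.bands),
            sigma_obs=sim.sigma_obs,
            effect=effect,
            rng_seed=cfg.rng_seed,
        )
        cohort = simulate_cohort(spec)
        subjects = [(s.subject_id, s.group, s.data) for s in cohort.subjects]
        return grid, subjects, spec.fs
    cohort_dir = Path(cfg.cohort_dir)
    grid = plio.load_grid(cohort_dir / "grid.h5")
    manifest = plio.read_manifest(cohort_dir / "manifest.tsv")
    subjects = []
    fs = None
    for _, row in manifest.iterrows():
        path = cohort_dir / (row["path"] or f"{row['subject_id']}.h5")
        data, fs, sid = plio.load_continuous(path)
        subjects.append((sid, row["group"], data))
    return grid, subjects, fs


def _resolve_seeds(cfg: RunConfig, grid: SourceGrid) -> list[SeedROI]:
    out = []
    for s in cfg.seeds:
        if s.source_indices is not None:
            out.append(
                SeedROI(
                    name=s.name,
                    laterality=s.laterality,
                    source_indices=np.asarray(s.source_indices),
                )
            )
        else:
            idx = build_rsn(grid, s.name, s.centers, s.radius).source_indices
            out.append(SeedROI(name=s.name, laterality=s.laterality, source_indices=idx))
    return out


def _resolve_rsns(cfg: RunConfig, grid: SourceGrid):
    rsns = []
    if cfg.rsn_file is not None:
        for item in load_roi_definitions(cfg.rsn_file, grid):
            rsns.append(item)
    elif cfg.use_default_rsns:
        defaults = default_rsn_coordinates()
        for net in defaults["networks"]:
            rsns.append(
                build_rsn(grid, net["name"], net["centers"], defaults.get("radius_mm", 15.0))
            )
    return rsns


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every enabled stage in order and write the run report."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=cfg.model_dump())
    from . import __version__

    report.version = __version__
    bands = [BandSpec(b.name, b.lo, b.hi) for b in cfg.bands]

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - stage tag then re-raise
                plio.write_json(out_dir / "report.json", report.to_dict())
                raise StageError(name, exc) from exc
            report.timings[name] = time.perf_counter() - t0
            return fn

        return deco

    state: dict = {}

    @stage("cohort")
    def _cohort():
        state["grid"], state["subjects"], state["fs"] = _build_cohort(cfg)

    grid: SourceGrid = state["grid"]
    subjects = state["subjects"]
    fs = state["fs"]
    groups = [g for _, g, _ in subjects]
    seeds = _resolve_seeds(cfg, grid)
    rsns = _resolve_rsns(cfg, grid)
    adjacency = build_adjacency(grid)

    @stage("connectivity")
    def _connectivity():
        # per band: seed FC vectors (streamed, seed rows only) and RSN values
        seed_vectors: dict = {b.name: {s.name: [] for s in seeds} for b in bands}
        rsn_values: dict = {b.name: {r.name: [] for r in rsns} for b in bands}
        for sid, group, data in subjects:
            for band in bands:
                z = analytic_epochs(
                    data, fs, band, epoch_len=cfg.epoch_len,
                    max_epochs=cfg.max_epochs, pad=cfg.pad, subject_id=sid,
                )
                for seed in seeds:
                    seed_vectors[band.name][seed.name].append(
                        seed_fc_from_analytic(z, seed, sid, band.name)
                    )
                if rsns:
                    from .preprocessing import PhaseSet

                    ph = PhaseSet(
                        subject_id=sid, band=band, data=np.angle(z),
                        fs=fs, epoch_len=cfg.epoch_len,
                    )
                    pm = plv_matrix(ph)
                    for rsn in rsns:
                        rsn_values[band.name][rsn.name].append(
                            rsn_fc(pm, rsn, cfg.pair_policy)
                        )
        state["seed_vectors"] = seed_vectors
        state["rsn_values"] = rsn_values

    @stage("seed_inference")
    def _seed_inference():
        results = {}
        for band in bands:
            for seed in seeds:
                vecs = state["seed_vectors"][band.name][seed.name]
                values = np.stack([v.values for v in vecs])
                distant = vecs[0].source_indices
                adj_sub = restrict_adjacency(adjacency, distant)
                cbpt = CBPTConfig(
                    cluster_forming_alpha=cfg.cbpt.cluster_forming_alpha,
                    n_permutations=cfg.cbpt.n_permutations,
                    rng_seed=cfg.rng_seed,
                    t_variant=cfg.cbpt.t_variant,
                    max_stat=cfg.cbpt.max_stat,
                )
                clusters = cluster_permutation_test(
                    values, groups, adj_sub, cbpt,
                    group_order=GROUP_ORDER, seed=seed.name, band=band.name,
                )
                results[f"{seed.name}/{band.name}"] = {
                    "clusters": [
                        {
                            "sources": distant[c.indices].tolist(),
                            "mass": c.mass,
                            "sign": c.sign,
                            "p": c.p_value,
                            "n_permutations": c.n_permutations,
                        }
                        for c in clusters
                    ],
                    "rng_seed": cfg.rng_seed,
                }
        report.seed_results = results
        plio.write_json(out_dir / "seed_clusters.json", results)

    @stage("rsn_inference")
    def _rsn_inference():
        results = {}
        for band in bands:
            for rsn in rsns:
                vals = state["rsn_values"][band.name][rsn.name]
                arr = np.array([v.value for v in vals])
                res = rsn_group_test(
                    arr, groups, network=rsn.name, band=band.name,
                    group_order=GROUP_ORDER, variant=cfg.cbpt.t_variant,
                )
                results[f"{rsn.name}/{band.name}"] = {
                    "mean_robust": res.mean1,
                    "mean_frail": res.mean2,
                    "t": res.t,
                    "p": res.p,
                    "n_pairs": vals[0].n_pairs,
                }
        report.rsn_results = results
        plio.write_json(out_dir / "rsn_tests.json", results)
        if results:
            import pandas as pd

            rows = [
                {"analysis": k, **v} for k, v in sorted(results.items())
            ]
            pd.DataFrame(rows).to_csv(out_dir / "rsn_tests.tsv", sep="\t", index=False)

    @stage("clinical")
    def _clinical():
        if not cfg.clinical:
            return
        table = simulate_clinical(
            n_robust=len([g for g in groups if g == "robust"]),
            n_frail=len([g for g in groups if g == "frail"]),
            rng_seed=cfg.rng_seed + 1,
        )
        rows = summarize(table, group_order=GROUP_ORDER)
        report.clinical_rows = [
            {
                "variable": r.variable,
                "robust": r.summary1,
                "frail": r.summary2,
                "test": r.test,
                "p": r.p,
            }
            for r in rows
        ]
        comparison_frame(rows, GROUP_ORDER).to_csv(
            out_dir / "clinical.tsv", sep="\t", index=False
        )

    plio.write_json(out_dir / "report.json", report.to_dict())
    return report
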