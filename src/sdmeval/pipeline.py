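"""End-to-end pipeline: synthetic data -> panel fits -> three-way
evaluation -> mixed-model synthesis, driven by one run configuration.

The stages mirror the evaluation framework: generate (or load) an
environmental stack, screen it for collinearity, build the virtual-
species pool with target-group background, fit the replicated algorithm
panel plus consensus, evaluate model fit (AUC), geographic consistency
(pairwise map agreement at three scales) and variable-importance
consistency (DFAC), and synthesize everything into the contrast summary
matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geodata, importance_eval, map_eval, sdm_engine, synthdata, synthesis

logger = logging.getLogger("sdmeval")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Structured run configuration (YAML-serializable).

    Defaults reproduce the reference experimental design: a ~10-layer
    1 km² environment, 16 virtual species spanning 6–2094 records, ten
    replicate 75/25 splits (fewer for data-poor species), the full
    six-algorithm panel plus consensus, 4-cell fuzzy neighborhood, and
    five permutations per variable for importance.
    """

    seed: int = 0
    # synthetic environment
    n_layers: int = 10
    shape: tuple[int, int] = (100, 100)
    autocorr_range_cells: float = 5.0
    cell_size_km: float = 1.0
    # species pool
    record_counts: tuple[int, ...] = synthdata.DEFAULT_RECORD_COUNTS
    n_drivers: int = 2
    breadth_sd: float = 0.75
    # collinearity screen
    collinearity_cutoff: float = 0.7
    # engine
    algorithms: tuple[str, ...] = sdm_engine.ALGORITHMS
    n_replicates: int = 10
    train_frac: float = 0.75
    pa_factor: int = 10
    pa_max: int | None = None
    include_consensus: bool = True
    hyperparameters: dict = field(default_factory=dict)
    # map evaluation
    radius_cells: float = 4.0
    halving_distance_cells: float = 2.0
    fuzzy_null_draws: int = 2000
    # importance
    n_permutations: int = 5
    # synthesis
    interactions: bool = True

    def engine_config(self) -> sdm_engine.EngineConfig:
        return sdm_engine.EngineConfig(
            n_replicates=self.n_replicates, train_frac=self.train_frac,
            pa_factor=self.pa_factor, pa_max=self.pa_max,
            include_consensus=self.include_consensus,
            hyperparameters=self.hyperparameters)

    def scale_settings(self) -> map_eval.ScaleSettings:
        return map_eval.ScaleSettings(
            radius_cells=self.radius_cells,
            halving_distance_cells=self.halving_distance_cells,
            n_null=self.fuzzy_null_draws, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key in ("shape", "record_counts", "algorithms"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def desk_scale_config(seed: int = 0) -> RunConfig:
    """Desk-scale profile: the full design (16 species, 10 layers,
    100 x 100 grid, complete panel plus consensus) with sizes chosen to
    run end-to-end on a single CPU in minutes — two replicate splits for
    data-rich species, a pseudo-absence cap, smaller boosting/ANN search
    budgets and a reduced Monte-Carlo null for the fuzzy Kappa."""
    return RunConfig(
        seed=seed,
        n_replicates=2,
        pa_max=300,
        hyperparameters={
            "GBM": {"n_trees_max": 150, "cv_folds": 3},
            "ANN": {"decay_grid": (0.01, 0.1), "units_grid": (4,),
                    "cv_folds": 2, "max_iter": 100},
        },
        fuzzy_null_draws=30,
        n_permutations=2,
    )


# ---------------------------------------------------------------------------
# Pipeline result and stages
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: RunConfig
    stack: geodata.EnvStack
    retained_layers: list[str]
    pool: synthdata.SpeciesPool
    experiment: sdm_engine.ExperimentResult
    auc_frame: pd.DataFrame
    similarity_frame: pd.DataFrame
    importance_frame: pd.DataFrame
    dfac_frame: pd.DataFrame
    eval_dataset: pd.DataFrame
    lme_results: list[synthesis.LmeResult]
    summary: pd.DataFrame

    def species_covariates(self) -> pd.DataFrame:
        return _species_covariates(self.stack, self.pool)


def _species_covariates(stack: geodata.EnvStack,
                        pool: synthdata.SpeciesPool) -> pd.DataFrame:
    rows = []
    for sid, occ in pool.occurrences.items():
        pts = stack.cell_centers_km(occ.presence_cells)
        q3 = synthdata.q3_distance(pts) if len(pts) >= 2 else 0.0
        rows.append(dict(species_id=sid, n_records=occ.n_records,
                         q3_distance_km=q3,
                         species_class=pool.classes[sid].label))
    return pd.DataFrame(rows)


def run_all(config: RunConfig, out_dir: str | Path | None = None,
            stack: geodata.EnvStack | None = None) -> PipelineResult:
    """Run every stage; optionally write text outputs under ``out_dir``."""
    cfg = config
    if stack is None:
        stack = synthdata.generate_env_stack(
            cfg.n_layers, cfg.shape, cfg.autocorr_range_cells,
            seed=sdm_engine.derive_seed(cfg.seed, "env"),
            cell_size_km=cfg.cell_size_km)
    retained = geodata.collinearity_filter(stack, cfg.collinearity_cutoff)
    stack_r = stack.subset(retained)
    logger.info("retained %d/%d layers after collinearity screen",
                len(retained), stack.n_layers)

    pool = synthdata.generate_species_pool(
        stack_r, seed=sdm_engine.derive_seed(cfg.seed, "pool"),
        record_counts=cfg.record_counts, n_drivers=cfg.n_drivers,
        breadth_sd=cfg.breadth_sd)

    importance_rows: list[pd.Series] = []

    def on_run(run: sdm_engine.ModelRun, table: geodata.FeatureTable) -> None:
        prof = importance_eval.importance_profile(
            run, table, n_perm=cfg.n_permutations, master_seed=cfg.seed)
        run.importance = prof
        importance_rows.append(prof)

    experiment = sdm_engine.run_experiment(
        stack_r, pool, algorithm_panel=cfg.algorithms,
        config=cfg.engine_config(), master_seed=cfg.seed, on_run=on_run)

    auc_frame = pd.DataFrame([
        dict(species_id=r.species_id, algorithm_id=r.algorithm_id,
             replicate=r.replicate, auc=r.auc, threshold=r.threshold)
        for r in experiment.runs
    ])

    # pairwise map agreement per species x algorithm
    sim_records = []
    settings = cfg.scale_settings()
    algorithms_all = list(cfg.algorithms)
    if cfg.include_consensus:
        algorithms_all.append(sdm_engine.CONSENSUS_ID)
    for sid in pool.species_ids:
        for alg in algorithms_all:
            maps = [r.binary_map for r in experiment.runs_for(sid, alg)
                    if r.binary_map is not None]
            if alg == sdm_engine.CONSENSUS_ID:
                # one ensemble map voted over all replicates: replicate
                # "maps" are identical by construction, so pairwise
                # agreement is trivially maximal; skip.
                continue
            if len(maps) >= 2:
                sim_records.extend(map_eval.pairwise_similarity(maps, settings))
    similarity_frame = map_eval.similarity_to_frame(sim_records)

    # importance and DFAC (single algorithms only)
    importance_frame = _importance_frame(importance_rows)
    dfac_frame = _dfac_frame(importance_frame)

    covariates = _species_covariates(stack_r, pool)
    eval_dataset = synthesis.build_eval_dataset(
        auc_frame, similarity_frame, dfac_frame, covariates)

    lme_results = []
    for resp in synthesis.RESPONSES:
        sub = eval_dataset[eval_dataset["response_name"] == resp]
        if sub.empty or sub["algorithm_id"].nunique() < 2:
            continue
        try:
            lme_results.append(synthesis.fit_lme(
                eval_dataset, resp, interactions=cfg.interactions))
        except ValueError as exc:
            logger.warning("synthesis skipped %s: %s", resp, exc)
    summary = synthesis.summary_table(lme_results)

    result = PipelineResult(
        config=cfg, stack=stack, retained_layers=retained, pool=pool,
        experiment=experiment, auc_frame=auc_frame,
        similarity_frame=similarity_frame,
        importance_frame=importance_frame, dfac_frame=dfac_frame,
        eval_dataset=eval_dataset, lme_results=lme_results, summary=summary)
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def _importance_frame(rows: list[pd.Series]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=["species_id", "algorithm_id",
                                     "replicate", "variable",
                                     "importance_pct"])
    recs = []
    for s in rows:
        sid, alg, rep = s.name
        for var, val in s.items():
            recs.append(dict(species_id=sid, algorithm_id=alg, replicate=rep,
                             variable=var, importance_pct=val))
    return pd.DataFrame(recs)


def _dfac_frame(importance_frame: pd.DataFrame) -> pd.DataFrame:
    if importance_frame.empty:
        return pd.DataFrame(columns=["species_id", "algorithm_id", "variable",
                                     "replicate", "deviance"])
    out = []
    for (sid, alg), grp in importance_frame.groupby(
            ["species_id", "algorithm_id"]):
        mat = grp.pivot(index="replicate", columns="variable",
                        values="importance_pct")
        if len(mat) < 2:
            continue
        d = importance_eval.dfac(mat)
        d["species_id"] = sid
        d["algorithm_id"] = alg
        d["replicate"] = mat.index.to_numpy()[d["replicate"].to_numpy()]
        out.append(d)
    if not out:
        return pd.DataFrame(columns=["species_id", "algorithm_id", "variable",
                                     "replicate", "deviance"])
    return pd.concat(out, ignore_index=True)[
        ["species_id", "algorithm_id", "variable", "replicate", "deviance"]]


def write_outputs(result: PipelineResult, out_dir: str | Path,
                  write_maps: bool = False) -> None:
    """Write the evaluation tables, ledger and summary as CSV/text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.experiment.ledger.to_csv(out / "ledger.csv", index=False)
    result.auc_frame.to_csv(out / "auc.csv", index=False)
    result.similarity_frame.to_csv(out / "map_similarity.csv", index=False)
    result.importance_frame.to_csv(out / "importance.csv", index=False)
    result.dfac_frame.to_csv(out / "dfac.csv", index=False)
    result.eval_dataset.to_csv(out / "eval_dataset.csv", index=False)
    result.summary.to_csv(out / "summary_matrix.csv")
    result.species_covariates().to_csv(out / "species.csv", index=False)
    synthdata.write_pool_csv(result.pool, out / "occurrences.csv",
                             nrows=result.stack.shape[0],
                             cell_size_km=result.stack.cell_size_km)
    with open(out / "report.txt", "w") as fh:
        fh.write("Algorithm contrast summary\n")
        fh.write("==========================\n\n")
        fh.write(result.summary.to_string())
        fh.write("\n\nMean AUC by algorithm\n---------------------\n")
        fh.write(result.auc_frame.groupby("algorithm_id")["auc"]
                 .mean().round(4).to_string())
        fh.write("\n")
    if write_maps:
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        for run in result.experiment.runs:
            if run.binary_map is None:
                continue
            name = f"{run.species_id}_{run.algorithm_id}_r{run.replicate}.asc"
            geodata.write_ascii_grid(maps_dir / name,
                                     run.binary_map.grid.astype(float),
                                     result.stack.cell_size_km)
    logger.info("outputs written to %s", out)
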