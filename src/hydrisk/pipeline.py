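"""Ingestion filters, pipeline orchestration and provenance.

``ingest_trait_records`` applies the record-level quality filters (stem
tissue, mature individuals, and for P50/P88 a -0.5 MPa ceiling with
S-shaped vulnerability curves) before averaging to species values.
``run_pipeline`` drives the synthetic-mode pipeline end to end —
simulate -> features -> impute -> aggregate -> relate -> project — writing
per-stage artifacts and a manifest (config, seeds, file hashes) so every
output is traceable and re-runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import assemblage as asm
from . import envfeat, maxent, mortality, phylo
from .impute import ImputationSpec, best_spec, compute_hsm, cross_validate_specs, impute_traits_ensemble
from .synthetic import SyntheticWorldConfig, simulate_world

log = logging.getLogger("hydrisk")

__all__ = ["ingest_trait_records", "run_pipeline", "default_specs", "feature_table"]


def ingest_trait_records(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Filter raw trait records and average to one value per species+trait.

    Expected columns: species, trait (p_min | p50 | p88), value (MPa),
    tissue, maturity, curve_shape. Filters: stem tissue and mature
    individuals for all traits; for p50/p88 additionally value < -0.5 MPa
    from S-shaped curves. Malformed rows are skipped and counted.
    """
    counts = {"input": len(records)}
    required = {"species", "trait", "value"}
    rec = records.copy()
    bad = rec[list(required)].isna().any(axis=1)
    bad |= ~pd.to_numeric(rec["value"], errors="coerce").notna()
    counts["malformed"] = int(bad.sum())
    rec = rec[~bad]
    rec["value"] = rec["value"].astype(float)

    keep = pd.Series(True, index=rec.index)
    if "tissue" in rec.columns:
        keep &= rec["tissue"].str.lower() == "stem"
    if "maturity" in rec.columns:
        keep &= rec["maturity"].str.lower() == "mature"
    counts["failed_tissue_maturity"] = int((~keep).sum())
    rec = rec[keep]

    vuln = rec["trait"].isin(["p50", "p88"])
    ok = ~vuln | (
        (rec["value"] < -0.5)
        & (rec.get("curve_shape", pd.Series("S", index=rec.index)).astype(str).str.upper() == "S")
    )
    counts["failed_vulnerability_filter"] = int((~ok).sum())
    rec = rec[ok]
    counts["retained"] = len(rec)

    table = rec.pivot_table(index="species", columns="trait", values="value", aggfunc="mean")
    table.columns.name = None
    return table, counts


def default_specs(n_trees: int = 100, phylo_axes: int = 5, env_components: int = 5) -> list[ImputationSpec]:
    """The predictor-set grid compared by cross-validation."""
    return [
        ImputationSpec("phylo+env+clade", phylo_axes, env_components, True, n_trees=n_trees),
        ImputationSpec("phylo_only", phylo_axes, 0, False, n_trees=n_trees),
        ImputationSpec("env_only", 0, env_components, False, n_trees=n_trees),
    ]


def feature_table(world, phylo_axes: int = 5, env_components: int = 5) -> pd.DataFrame:
    """Species table: clade + phylogenetic axes + env components + traits."""
    d = phylo.cophenetic_distances(world.phylogeny.genus_tree)
    scores = phylo.pcoa(d, n_axes=phylo_axes)
    sp_scores = phylo.assign_species_scores(scores, world.phylogeny.species_to_genus)
    env_tab, _ = envfeat.normalize_transform(world.species_env_means)
    pca = envfeat.env_pca(env_tab, n_components=env_components)
    table = sp_scores.join(pca.scores, how="inner")
    table = table.join(world.traits_observed[["clade", "p_min", "p50", "p88"]], how="inner")
    return table


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the toggled stages on a synthetic world; write a manifest.

    ``config`` keys: ``seed``; ``world`` (SyntheticWorldConfig fields);
    ``stages`` (list among simulate, features, impute, aggregate, relate,
    project); ``impute``/``relate``/``project`` parameter blocks. Any stage
    failure aborts with the stage name in the raised error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get(
        "stages", ["simulate", "features", "impute", "aggregate", "relate", "project"]
    )
    manifest: dict = {"seed": seed, "stages": {}, "config": config}
    state: dict = {}

    def stage(name):
        def deco(fn):
            if name in stages:
                t0 = time.time()
                try:
                    fn()
                except Exception as exc:  # noqa: BLE001
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
                log.info("stage %s done in %.1fs", name, time.time() - t0)
            return fn
        return deco

    @stage("simulate")
    def _simulate():
        world_cfg = dict(config.get("world", {}))
        world_cfg["seed"] = seed
        world_cfg["grid_shape"] = tuple(world_cfg.get("grid_shape", (40, 40)))
        world = simulate_world(SyntheticWorldConfig(**world_cfg))
        state["world"] = world
        world.env.write(outdir / "env")
        world.phylogeny.tree.write(path=str(outdir / "tree.nwk"), schema="newick")
        world.traits_observed.to_csv(outdir / "traits_observed.csv")
        world.traits_truth.to_csv(outdir / "traits_truth.csv")
        pd.DataFrame(
            [(s, c) for s, cells in world.ranges.cells.items() for c in cells],
            columns=["species", "cell"],
        ).to_csv(outdir / "ranges.csv", index=False)
        world.mortality.to_csv(outdir / "mortality.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(world.truth, indent=1, default=str))

    @stage("features")
    def _features():
        k = config.get("impute", {})
        state["features"] = feature_table(
            state["world"], k.get("phylo_axes", 5), k.get("env_components", 5)
        )
        state["features"].to_csv(outdir / "features.csv")

    @stage("impute")
    def _impute():
        k = config.get("impute", {})
        specs = default_specs(
            k.get("n_trees", 100), k.get("phylo_axes", 5), k.get("env_components", 5)
        )
        report = cross_validate_specs(
            state["features"], specs,
            test_fractions=k.get("test_fractions", [0.1]),
            reps=k.get("cv_reps", 5), seed=seed,
        )
        report.to_csv(outdir / "cv_report.csv", index=False)
        chosen = best_spec(report, specs)
        completed = impute_traits_ensemble(
            state["features"], chosen, n_iter=k.get("ensemble_iters", 10), seed=seed
        )
        completed["p88"] = state["world"].traits_observed["p88"]
        completed = compute_hsm(completed)
        state["traits"] = completed
        state["cv_report"] = report
        completed.to_csv(outdir / "traits_completed.csv")

    @stage("aggregate")
    def _aggregate():
        world = state["world"]
        grid = asm.compute_assemblage_grid(
            world.occupancy, world.ranges.species, state["traits"], world.config.grid_shape
        )
        state["grid"] = grid
        grid.write(outdir / "assemblage")

    @stage("relate")
    def _relate():
        k = config.get("relate", {})
        world, grid = state["world"], state["grid"]
        table = grid.flat_table()
        table["biome"] = pd.Categorical(world.biome.ravel())
        pres = world.mortality["cell"].to_numpy()
        summary = mortality.assemblage_mortality_models(
            table[["n_hsm_neg", "richness", "biome"]],
            pres, "n_hsm_neg + richness",
            reps=k.get("reps", 20), seed=seed, eval_reps=k.get("eval_reps", 5),
        )
        state["relate"] = summary
        summary.coefficients.to_csv(outdir / "assemblage_glm_coefficients.csv")
        (outdir / "assemblage_glm.json").write_text(json.dumps(
            {"pseudo_r2": summary.pseudo_r2, "auc": summary.auc,
             "iterations": summary.iterations, **summary.extra}, indent=1))

    @stage("project")
    def _project():
        k = config.get("project", {})
        world, grid = state["world"], state["grid"]
        table = grid.flat_table()
        table["biome"] = world.biome.ravel().astype(str)
        table["pft"] = world.pft.ravel().astype(str)
        for i, name in enumerate(world.env.names):
            table[name] = world.env.flat()[i]
        table = table.dropna(subset=["n_hsm_neg", "var_hsm"])
        pres_cells = np.unique(world.mortality["cell"].to_numpy())
        pres_cells = pres_cells[np.isin(pres_cells, table.index)]
        rng = np.random.default_rng(seed)
        candidates = table.index.difference(pres_cells)
        n_bg = min(k.get("n_background", 1000), len(candidates))
        bg_cells = rng.choice(candidates, size=n_bg, replace=False)
        suite = maxent.run_model_suite(
            table.loc[pres_cells], table.loc[bg_cells],
            factor_vars=["biome", "pft"],
            continuous_vars=k.get("continuous_vars", world.env.names[:4]),
            hydraulic_vars=["n_hsm_neg", "var_hsm"],
            reps=k.get("reps", 10), seed=seed,
            n_knots=k.get("n_knots", 15), tol=k.get("tol", 1e-4),
        )
        state["suite"] = suite
        report = {
            name: {
                "test_auc_mean": suite[name]["test_auc_mean"],
                "test_auc_sd": suite[name]["test_auc_sd"],
                "contribution": suite[name]["contribution"].to_dict(),
                "permutation_importance": suite[name]["permutation_importance"].to_dict(),
            }
            for name in ("a", "b", "c")
        }
        (outdir / "maxent_suite.json").write_text(json.dumps(report, indent=1))

    manifest["files"] = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    state["manifest"] = manifest
    return state
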