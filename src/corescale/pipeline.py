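"""End-to-end strategy runner.

Stages: obtain genotypic values (load, or adjust observed data, or simulate)
-> Monte Carlo surface -> candidate formula fits -> selection -> inversion
at the CR threshold -> treat-vs-CK validation and PCA projection.  All
artifacts are written as delimited text under one output directory with a
JSON manifest recording seeds, versions and the config hash.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjust import adjust
from .config import RunConfig
from .formulas import fit_families, invert_at_threshold, select_formula
from .io import read_observed, read_trait_matrix, write_trait_matrix
from .surface import SurfaceConfig, simulate_surface
from .synthetic import SyntheticConfig, generate
from .validate import compare_treat_ck, project_pca
from .sampling import ldss_sample

__all__ = ["run_strategy"]


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=tuple(stage.encode()))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_strategy(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"package": "corescale", "version": __version__,
                "config_digest": config.digest(), "seed": config.seed,
                "stages": []}

    def note(stage, **info):
        manifest["stages"].append({"stage": stage, **info})
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        if config.trait_matrix:
            matrix = read_trait_matrix(config.trait_matrix)
            note("load", source=str(config.trait_matrix))
        elif config.observed:
            observed = read_observed(config.observed)
            result = adjust(observed)
            matrix = result.genotypic
            note("adjust", method=result.method_label,
                 n_accessions=matrix.n_accessions)
        else:
            syn_seed = _stage_seed(config.seed, "synthetic")
            observed, matrix = generate(SyntheticConfig(seed=syn_seed))
            note("simulate", seed=syn_seed, n_accessions=matrix.n_accessions,
                 n_traits=matrix.n_traits)
        write_trait_matrix(matrix, outdir / "trait_matrix.tsv")

        scfg = SurfaceConfig(percentages=config.percentages,
                             trait_counts=config.trait_counts,
                             replications=config.replications,
                             metric=config.metric,
                             parameter=config.parameter,
                             base_seed=_stage_seed(config.seed, "surface"))
        surf = simulate_surface(matrix, scfg)
        surf.to_dataframe().to_csv(outdir / "surface.tsv", sep="\t",
                                   float_format="%.10g")
        surf.long_replicates().to_csv(outdir / "surface_replicates.tsv",
                                      sep="\t", index=False,
                                      float_format="%.10g")
        note("surface", base_seed=scfg.base_seed, cells=scfg.n_cells,
             replications=scfg.replications)

        fits = fit_families(surf, seed=_stage_seed(config.seed, "fit"))
        pd.DataFrame([{
            "family": f.family_id, "size": f.size, "error": f.error,
            "rmse": f.rmse, "r2": f.r2, "converged": f.converged,
            "expression": f.expression,
            "params": ",".join(f"{v:.6g}" for v in f.params),
        } for f in fits]).to_csv(outdir / "fits.tsv", sep="\t", index=False,
                                 float_format="%.10g")
        selected = select_formula(fits, r2_floor=config.r2_floor,
                                  error_tolerance=config.error_tolerance)
        note("select", family=selected.family_id, r2=selected.r2,
             error=selected.error)

        curve = invert_at_threshold(selected, config.cr_threshold,
                                    config.trait_counts,
                                    fitted_percentages=config.percentages)
        pd.DataFrame({
            "trait_count": curve.trait_counts,
            "optimal_percentage": curve.rounded(2),
            "defined": curve.defined,
            "note": curve.notes,
        }).to_csv(outdir / "optimal_curve.tsv", sep="\t", index=False)
        note("invert", cr_threshold=config.cr_threshold,
             family=curve.family_id)

        val_pcts = list(config.validation_percentages)
        optimal_at_max = curve.percentages[-1]
        if curve.defined[-1] and np.isfinite(optimal_at_max):
            val_pcts = [round(float(optimal_at_max), 2)] + val_pcts
        seeds = [_stage_seed(config.seed, f"validate-{i}")
                 for i in range(config.validation_seeds)]
        table = compare_treat_ck(matrix, val_pcts, seeds,
                                 metric=config.metric, alpha=config.alpha)
        table.to_csv(outdir / "validation.tsv", sep="\t", index=False,
                     float_format="%.10g")
        core = ldss_sample(matrix, val_pcts[0], metric=config.metric,
                           seed=seeds[0])
        proj = project_pca(matrix, core.selected)
        proj.to_dataframe().to_csv(outdir / "pca_projection.tsv", sep="\t",
                                   index=False, float_format="%.10g")
        manifest["pca_explained_percent"] = [float(v) for v
                                             in proj.explained_percent]
        manifest["optimal_percentages"] = {
            str(y): (round(float(x), 2) if d else None)
            for y, x, d in zip(curve.trait_counts, curve.percentages,
                               curve.defined)}
        note("validate", percentages=val_pcts, seeds=len(seeds))
    except Exception as exc:
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else "load"
        raise RuntimeError(
            f"pipeline aborted after stage {stage!r}: {exc}") from exc
    return manifest
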