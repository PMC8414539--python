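"""End-to-end pipeline: simulate (or load) DWI and cohort, fit free water,
extract tract metrics, run the association cascade, write a manifest.

Stage failures abort with the stage name and cause.  The pipeline runs at
desk scale: one synthetic multi-region phantom exercises the imaging path
(fit + ROI extraction on its own region masks), while the statistics
cascade runs on a simulated cohort carrying the full 55 tract-metric
columns.  Rerunning with the same config and seed reproduces every output
checksum.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSimConfig, simulate_cohort
from .config import PipelineConfig
from .freewater import FreeWaterOptions, corrected_scalars, fit_free_water
from .gradients import make_gradient_table, read_fsl_gradients
from .io import (
    load_nifti,
    save_flags,
    save_scalar_maps,
    sha256_of,
    write_csv,
    write_phantom,
)
from .phantom import make_phantom, recovery_phantom_spec
from .roi import TractAtlas, extract_metrics, load_atlas, metric_columns, tidy_to_wide
from .stats import (
    backward_stepwise,
    competitive_models,
    run_primary_analysis,
    select_stepwise_candidates,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


def _stage(name):
    def wrap(fn, *args, **kwargs):
        log.info("stage %s: start", name)
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s: done", name)
        return out

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the output manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    missing = [str(p) for p in config.input_paths() if not p.exists()]
    if missing:
        raise PipelineError(f"pre-flight check failed; missing inputs: {missing}")

    manifest: dict = {
        "package": "fwtract",
        "version": __version__,
        "seed": config.seed,
        "inputs": config.to_dict(),
        "stages": {},
    }
    outputs: list[Path] = []

    # ---- imaging path -------------------------------------------------
    if config.dwi:
        def load_dwi():
            data, affine = load_nifti(config.dwi["dwi"])
            gtab = read_fsl_gradients(config.dwi["bval"], config.dwi["bvec"])
            return data, affine, gtab, None

        data, affine, gtab, phantom = _stage("load-dwi")(load_dwi)
    else:
        def simulate_dwi():
            opts = dict(config.phantom)
            n_dirs = opts.pop("n_dirs", 32)
            bval = opts.pop("bval", 1000.0)
            n_b0 = opts.pop("n_b0", 1)
            gtab = make_gradient_table(n_dirs, bval, n_b0)
            spec = recovery_phantom_spec(seed=config.seed, **opts)
            phantom = make_phantom(spec, gtab)
            paths = write_phantom(phantom, outdir / "dwi")
            outputs.extend(paths.values())
            return phantom.data, phantom.affine, gtab, phantom

        data, affine, gtab, phantom = _stage("simulate-dwi")(simulate_dwi)
    manifest["stages"]["dwi"] = {
        "shape": list(data.shape), "n_volumes": gtab.n_volumes,
    }

    def fit_stage():
        opts = FreeWaterOptions(**config.fit)
        b0_mean = data[..., gtab.b0_mask].mean(axis=-1)
        mask = b0_mean >= 0.2 * float(b0_mean.max())
        fit = fit_free_water(data, gtab, options=opts, mask=mask)
        maps = corrected_scalars(fit)
        paths = save_scalar_maps(maps, affine, outdir / "maps")
        paths["flags"] = save_flags(fit, affine, outdir / "maps" / "flags.nii.gz")
        outputs.extend(paths.values())
        return fit, maps

    fit, maps = _stage("fit-fw")(fit_stage)
    manifest["stages"]["fit_fw"] = {
        "n_voxels_fit": int((fit.flags == 0).sum()),
        "options": vars(fit.options).copy(),
    }

    def roi_stage():
        if config.templates:
            atlas = load_atlas(config.templates,
                               threshold=config.roi.get("threshold", 0.0))
        else:
            atlas = TractAtlas.from_arrays(phantom.masks, affine=affine)
        tidy = extract_metrics(maps, atlas,
                               statistic=config.roi.get("statistic", "mean"))
        outputs.append(write_csv(tidy, outdir / "roi_metrics_tidy.csv"))
        wide = tidy_to_wide(tidy, subject_id="phantom-001")
        outputs.append(write_csv(wide, outdir / "roi_metrics_wide.csv"))
        return tidy

    tidy = _stage("extract-roi")(roi_stage)
    manifest["stages"]["extract_roi"] = {
        "n_tracts": int(tidy["tract"].nunique()),
        "n_cells": int(len(tidy)),
    }

    # ---- cohort path --------------------------------------------------
    def cohort_stage():
        if config.cohort_csv:
            cohort = pd.read_csv(config.cohort_csv)
        else:
            cfg = CohortSimConfig(seed=config.seed + 1, **config.cohort)
            cohort = simulate_cohort(cfg)
            outputs.append(write_csv(cohort, outdir / "cohort.csv"))
        return cohort

    cohort = _stage("cohort")(cohort_stage)
    n_metric_cols = len([c for c in cohort.columns if c in metric_columns()])
    manifest["stages"]["cohort"] = {
        "n_subjects": int(len(cohort)),
        "n_metric_columns": n_metric_cols,
    }

    analysis = config.analysis
    covariates = tuple(analysis.get("covariates", ()))
    outcome = analysis.get("outcome", "scd_total")
    alpha = analysis.get("alpha", 0.05)
    csf = analysis.get("csf", "csf_abeta42")

    def associate_stage():
        table = run_primary_analysis(cohort, outcome=outcome,
                                     covariates=covariates)
        outputs.append(write_csv(table, outdir / "associations.csv"))
        return table

    assoc = _stage("associate")(associate_stage)
    manifest["stages"]["associate"] = {
        "n_models": int(len(assoc)),
        "n_fdr_significant": int((assoc["q"] < alpha).sum()),
    }

    if csf in cohort.columns and cohort[csf].notna().any():
        def competitive_stage():
            comp = competitive_models(cohort, covariates=covariates, csf=csf,
                                      outcome=outcome)
            outputs.append(write_csv(comp.table, outdir / "competitive.csv"))
            return comp

        comp = _stage("competitive")(competitive_stage)
        manifest["stages"]["competitive"] = {
            "base_r2adj_pct": 100.0 * comp.base_r2adj,
            "n_subjects": comp.n,
        }

        def stepwise_stage():
            # CSF Aβ42 competes alongside the covariates in selection
            candidates = select_stepwise_candidates(
                comp, covariates=[*covariates, csf], alpha=alpha
            )
            result = backward_stepwise(cohort, candidates, outcome=outcome)
            trace = pd.DataFrame(
                [{"step": 0, "removed": "", "r2adj": result.initial_r2adj}]
                + [
                    {"step": i + 1, "removed": var, "r2adj": r2}
                    for i, (var, r2) in enumerate(result.trace)
                ]
            )
            outputs.append(write_csv(trace, outdir / "stepwise_trace.csv"))
            return result

        step = _stage("stepwise")(stepwise_stage)
        manifest["stages"]["stepwise"] = {
            "selected": list(step.selected),
            "final_r2adj_pct": 100.0 * step.final_r2adj,
        }

    manifest["checksums"] = {
        str(Path(p).relative_to(outdir)): sha256_of(p) for p in outputs
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
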