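"""End-to-end orchestration: simulate/load -> preprocess -> indices ->
stability -> per-angle linear fits -> multi-angle models.

Each stage writes its artifact before the next starts, so every number
in the bundle is traceable to a stage output file; a failure aborts with
the stage name.  The bundle is a pure function of (config, input files).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from mavi.angular_analysis import stability_report
from mavi.config import RunConfig
from mavi.errors import DataError, MaviError
from mavi.lai_models import SplitSpec, fit_linear_per_angle, fit_multiangle
from mavi.spectral_core import MultiAngleDataset, preprocess, read_dataset, write_dataset
from mavi.synth_canopy import BrdfParams, simulate_dataset
from mavi.vi_library import compute_index_table

log = logging.getLogger(__name__)


class StageError(MaviError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_or_simulate(config: RunConfig, spectra_path=None, metadata_path=None) -> MultiAngleDataset:
    if spectra_path is not None and metadata_path is not None:
        return read_dataset(spectra_path, metadata_path)
    brdf = BrdfParams(noise_sd=config.sim_noise_sd)
    return simulate_dataset(
        reps=config.sim_reps,
        stages=config.sim_stages,
        vzas=config.vzas,
        brdf=brdf,
        seed=config.sim_seed,
    )


def run_study(
    config: RunConfig,
    out_dir: str | Path,
    spectra_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
) -> dict:
    """Execute the full workflow and write the report bundle.

    Returns a summary dict (also written to ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.log_defaults()
    config.dump(out / "config.yaml")
    summary: dict = {"stages": []}

    def stage(name):
        log.info("stage %s", name)
        summary["stages"].append(name)

    try:
        stage("load")
        dataset = load_or_simulate(config, spectra_path, metadata_path)
        spectra_df, meta_df = write_dataset(dataset)
        meta_df.to_csv(out / "meta.csv", index=False)
        log.info("load: %d observations, %d samples", len(dataset), len(dataset.metadata))
    except MaviError as exc:
        raise StageError("load", exc) from exc

    try:
        stage("preprocess")
        dataset = preprocess(
            dataset,
            grid_step_nm=config.grid_step_nm,
            sg_window=config.sg_window,
            sg_polyorder=config.sg_polyorder,
        )
    except MaviError as exc:
        raise StageError("preprocess", exc) from exc

    try:
        stage("indices")
        vitable = compute_index_table(
            dataset, list(config.index_names), vlopt_variant=config.vlopt_variant
        )
        vitable.to_csv(out / "vitable.csv", index=False)
        log.info("indices: %d cells", len(vitable))
    except MaviError as exc:
        raise StageError("indices", exc) from exc

    vzas_present = sorted(vitable["vza_deg"].unique())
    if len(vzas_present) < 2 or 0.0 not in vzas_present:
        log.warning(
            "stability stage skipped: needs nadir plus at least one other VZA, found %s",
            vzas_present,
        )
        summary["stability"] = "skipped: fewer than two VZAs including nadir"
        report = None
    else:
        try:
            stage("stability")
            report = stability_report(vitable, dataset.metadata)
            report.to_dir(out / "stability")
        except MaviError as exc:
            raise StageError("stability", exc) from exc

    split = SplitSpec(train_fraction=config.train_fraction, seed=config.split_seed)
    index = config.multiangle_index

    try:
        stage("linear_fits")
        linear_rows = []
        for vza in vzas_present:
            fit = fit_linear_per_angle(vitable, dataset.metadata, index, vza, split)
            linear_rows.append(
                {
                    "vza_deg": vza,
                    "slope": fit.parameters["slope"],
                    "intercept": fit.parameters["intercept"],
                    "r2_train": fit.r2_train,
                    "r2_test": fit.r2_test,
                    "rmse_train": fit.rmse_train,
                    "rmse_test": fit.rmse_test,
                }
            )
        linear_df = pd.DataFrame(linear_rows)
        linear_df.to_csv(out / "linear_fits.csv", index=False)
    except MaviError as exc:
        raise StageError("linear_fits", exc) from exc

    try:
        stage("multiangle_fits")
        fits = {}
        angles = [v for v in config.multiangle_vzas if v in vzas_present]
        if len(angles) < 1:
            raise DataError(f"none of the requested angles {config.multiangle_vzas} present")
        for kind in config.model_kinds:
            hyper = {}
            if kind == "svr_rbf":
                hyper = {"C": config.svr_c, "epsilon": config.svr_epsilon}
            elif kind == "gbt":
                hyper = {
                    "max_depth": config.gbt_max_depth,
                    "learning_rate": config.gbt_learning_rate,
                    "n_estimators": config.gbt_n_estimators,
                    "alpha": config.gbt_alpha,
                    "lambda": config.gbt_lambda,
                }
            elif kind == "rf":
                hyper = {"n_trees": config.rf_n_trees, "mtry": config.rf_mtry}
            fit = fit_multiangle(
                vitable, dataset.metadata, index, angles, kind,
                split=split, seed=config.model_seed, **hyper,
            )
            fits[kind] = fit
            (out / f"fit_{kind}.json").write_text(json.dumps(fit.to_dict(), indent=2))
    except MaviError as exc:
        raise StageError("multiangle_fits", exc) from exc

    summary["n_samples"] = len(dataset.metadata)
    summary["n_observations"] = len(dataset)
    summary["index"] = index
    summary["best_linear"] = {
        "vza_deg": float(linear_df.loc[linear_df["r2_test"].idxmax(), "vza_deg"]),
        "r2_test": float(linear_df["r2_test"].max()),
    }
    summary["multiangle"] = {
        kind: {"r2_test": fit.r2_test, "rmse_test": fit.rmse_test} for kind, fit in fits.items()
    }
    if report is not None:
        summary["dr"] = {
            sub: {
                row["index"]: row["dr"]
                for _, row in report.dr[report.dr["sub_dataset"] == sub].iterrows()
            }
            for sub in report.dr["sub_dataset"].unique()
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
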