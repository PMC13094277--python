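"""Composable pipeline commands with validated config and run manifests.

Each command reads plain-text inputs (CSV/JSON), runs one pipeline stage and
writes its outputs plus a ``manifest.json`` describing exactly what ran:
command name, config echo, SHA-256 hashes of the inputs, seeds, package
version, wall-clock bounds and convergence flags.  Manifests are written even
when a stage fails, so every output directory is self-describing.

Stages: ``cmd_simulate`` (synthetic dataset), ``cmd_fit_sync`` (detection-
efficiency posterior + transfer priors), ``cmd_fit_ssm`` (occupancy
posterior + decoded presence), ``cmd_report`` (emigration series, fold
change, counts, variant comparison), ``cmd_recover`` (simulate-and-refit
replicates).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .mcmc import McmcConfig, PosteriorSamples, posterior_summary
from .occupancy import TransferPrior, fit_ssm
from .reporting import (
    fold_change,
    occupancy_counts,
    overall_emigration_summary,
    predict_emigration_series,
)
from .simulate import ScenarioConfig, recovery_experiment, simulate_study
from .sync_efficiency import (
    condition_covariates,
    covariate_diagnostics,
    export_transfer_priors,
    fit_sync_model,
    predict_detection_curve,
)
from .telemetry_io import (
    StudyWindow,
    build_covariate_table,
    build_hourly_matrix,
    build_pair_geometry,
    read_detections_csv,
    read_receivers_csv,
    sharks_per_hour,
)

__all__ = [
    "RunManifest",
    "cmd_simulate",
    "cmd_fit_sync",
    "cmd_fit_ssm",
    "cmd_report",
    "cmd_recover",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    started: str = ""
    finished: str = ""
    success: bool = False
    convergence_passed: bool | None = None
    error: str | None = None

    def write(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "manifest.json").write_text(json.dumps(asdict(self), indent=2, default=str))


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def _run(manifest: RunManifest, out_dir: Path, body) -> Path:
    manifest.started = _now()
    try:
        body()
        manifest.success = True
    except Exception as e:  # manifest written even on failure
        manifest.error = f"{type(e).__name__}: {e}"
        raise
    finally:
        manifest.finished = _now()
        manifest.write(out_dir)
    return out_dir


def cmd_simulate(config: ScenarioConfig, out_dir: str | Path) -> Path:
    """Generate a synthetic study and write it in the interchange CSV schemas."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("simulate", json.loads(config.model_dump_json()), config.seed)

    def body():
        study = simulate_study(config)
        pd.DataFrame(
            [
                {
                    "receiver_id": r.receiver_id,
                    "x": r.x,
                    "y": r.y,
                    "depth_m": r.depth_m,
                    "sync_tag_id": r.sync_tag_id or "",
                }
                for r in study.receivers
            ]
        ).to_csv(out / "receivers.csv", index=False)
        pd.DataFrame(
            [
                {
                    "animal_id": a.animal_id,
                    "sex": a.sex,
                    "length_cm": a.length_cm,
                    "tagging_date": a.tagging_date.date().isoformat(),
                    "tag_family": a.tag_family,
                }
                for a in study.animals
            ]
        ).to_csv(out / "animals.csv", index=False)
        study.env_frame.to_csv(out / "environment.csv", index=False)
        study.diag_frame.to_csv(out / "diagnostics.csv", index=False)

        def write_records(records, path):
            pd.DataFrame(
                {
                    "timestamp": [r.timestamp.isoformat() for r in records],
                    "receiver_id": [r.receiver_id for r in records],
                    "transmitter_id": [r.transmitter_id for r in records],
                }
            ).to_csv(path, index=False)

        write_records(study.animal_records(), out / "detections_animals.csv")
        write_records(study.sync_records(), out / "detections_sync.csv")
        scenario = json.loads(config.model_dump_json())
        scenario["_window"] = {
            "start": study.config.window.start.isoformat(),
            "end": study.config.window.end.isoformat(),
            "storm_start": study.config.storm_window.start.isoformat(),
            "storm_end": study.config.storm_window.end.isoformat(),
        }
        (out / "scenario.json").write_text(json.dumps(scenario, indent=2, default=str))
        truth = {
            "state": json.loads(config.state_truth.model_dump_json()),
            "obs": json.loads(config.obs_truth.model_dump_json()),
            "sync": json.loads(config.sync_truth.model_dump_json()),
            "theta_true": study.theta_true.tolist(),
            "alpha_true": study.alpha_true.tolist(),
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))

    return _run(manifest, out, body)


def _load_dataset(data_dir: Path):
    """Rebuild matrices, covariates and geometry from a simulate/field dataset dir."""
    scenario = json.loads((data_dir / "scenario.json").read_text())
    w = scenario["_window"]
    window = StudyWindow(
        start=pd.Timestamp(w["start"]).to_pydatetime(),
        end=pd.Timestamp(w["end"]).to_pydatetime(),
    )
    storm = StudyWindow(
        start=pd.Timestamp(w["storm_start"]).to_pydatetime(),
        end=pd.Timestamp(w["storm_end"]).to_pydatetime(),
    )
    receivers = read_receivers_csv(data_dir / "receivers.csv")
    geometry = build_pair_geometry(receivers)
    recv_ids = [r.receiver_id for r in receivers]
    animals = pd.read_csv(data_dir / "animals.csv")["animal_id"].astype(str).tolist()
    sync_tags = sorted({t for t, _ in geometry.pairs})

    animal_records = read_detections_csv(data_dir / "detections_animals.csv")
    sync_records = read_detections_csv(data_dir / "detections_sync.csv")
    animal_matrix = build_hourly_matrix(animal_records, animals, recv_ids, window)
    sync_matrix = build_hourly_matrix(sync_records, sync_tags, recv_ids, window)

    env = pd.read_csv(data_dir / "environment.csv")
    diag = pd.read_csv(data_dir / "diagnostics.csv")
    covariates = build_covariate_table(
        env, diag, sharks_per_hour(animal_matrix).astype(float), window,
        utc_offset_hours=int(scenario.get("utc_offset_hours", -7)),
    )
    return dict(
        window=window, storm=storm, receivers=receivers, geometry=geometry,
        animal_matrix=animal_matrix, sync_matrix=sync_matrix, covariates=covariates,
        scenario=scenario,
    )


def _input_hashes(data_dir: Path, names) -> dict[str, str]:
    return {n: _sha256(data_dir / n) for n in names if (data_dir / n).exists()}


_DATA_FILES = (
    "scenario.json", "receivers.csv", "animals.csv", "environment.csv",
    "diagnostics.csv", "detections_animals.csv", "detections_sync.csv",
)


def cmd_fit_sync(
    data_dir: str | Path,
    mcmc_config: McmcConfig,
    out_dir: str | Path,
    strict_convergence: bool = False,
) -> Path:
    """Fit the sync-tag detection-efficiency model; export transfer priors and
    counterfactual detection curves."""
    data_dir, out = Path(data_dir), Path(out_dir)
    manifest = RunManifest(
        "fit-sync", json.loads(mcmc_config.model_dump_json()), mcmc_config.seed,
        inputs=_input_hashes(data_dir, _DATA_FILES),
    )

    def body():
        ds = _load_dataset(data_dir)
        fit = fit_sync_model(ds["sync_matrix"], ds["covariates"], ds["geometry"],
                             mcmc_config=mcmc_config)
        manifest.convergence_passed = fit.convergence.passed
        if strict_convergence and not fit.convergence.passed:
            raise RuntimeError(
                f"sync model failed R-hat threshold (max {fit.convergence.max_rhat:.3f})"
            )
        out.mkdir(parents=True, exist_ok=True)
        fit.samples.to_dataframe().to_csv(out / "posterior.csv", index=False)
        (out / "convergence.json").write_text(json.dumps(fit.convergence.to_dict(), indent=2))
        transfer = export_transfer_priors(fit)
        (out / "transfer_prior.json").write_text(json.dumps(transfer.to_dict(), indent=2))
        conds = condition_covariates(ds["covariates"], ds["storm"])
        grid = np.linspace(50.0, 700.0, 66)
        curves = pd.concat(
            [
                predict_detection_curve(fit, grid, conds[c], condition=c).to_frame()
                for c in ("baseline", "storm")
            ],
            ignore_index=True,
        )
        curves.to_csv(out / "detection_curve.csv", index=False)
        corr, flags = covariate_diagnostics(ds["covariates"])
        corr.to_csv(out / "covariate_correlations.csv")
        (out / "collinearity_flags.json").write_text(json.dumps(flags, indent=2))

    return _run(manifest, out, body)


def cmd_fit_ssm(
    data_dir: str | Path,
    transfer_prior_path: str | Path | None,
    variant: str,
    mcmc_config: McmcConfig,
    out_dir: str | Path,
    strict_convergence: bool = False,
) -> Path:
    """Fit the occupancy state-space model (full or reduced variant)."""
    data_dir, out = Path(data_dir), Path(out_dir)
    inputs = _input_hashes(data_dir, _DATA_FILES)
    if transfer_prior_path is not None:
        inputs["transfer_prior.json"] = _sha256(Path(transfer_prior_path))
    manifest = RunManifest(
        "fit-ssm",
        {"variant": variant, **json.loads(mcmc_config.model_dump_json())},
        mcmc_config.seed, inputs=inputs,
    )

    def body():
        ds = _load_dataset(data_dir)
        transfer = None
        if variant == "full":
            if transfer_prior_path is None:
                raise ValueError("full variant requires --transfer-prior")
            transfer = TransferPrior.from_dict(
                json.loads(Path(transfer_prior_path).read_text())
            )
        fit = fit_ssm(ds["animal_matrix"], ds["covariates"], transfer,
                      variant=variant, mcmc_config=mcmc_config)
        manifest.convergence_passed = fit.convergence.passed
        if strict_convergence and not fit.convergence.passed:
            raise RuntimeError(
                f"occupancy model failed R-hat threshold (max {fit.convergence.max_rhat:.3f})"
            )
        out.mkdir(parents=True, exist_ok=True)
        fit.samples.to_dataframe().to_csv(out / "posterior.csv", index=False)
        (out / "convergence.json").write_text(json.dumps(fit.convergence.to_dict(), indent=2))
        hours = ds["animal_matrix"].window.hours
        occ_rows = []
        for i, animal in enumerate(fit.animals):
            occ_rows.append(
                pd.DataFrame(
                    {"animal": animal, "hour_start": hours, "p_present": fit.occupancy[i]}
                )
            )
        pd.concat(occ_rows, ignore_index=True).to_csv(out / "occupancy.csv", index=False)
        meta = {
            "variant": variant,
            "data_hash": fit.data_hash,
            "animals": fit.animals,
            "receivers": fit.receivers,
            "mcmc": json.loads(mcmc_config.model_dump_json()),
        }
        (out / "fit_meta.json").write_text(json.dumps(meta, indent=2))

    return _run(manifest, out, body)


def _load_ssm_fit(fit_dir: Path):
    meta = json.loads((fit_dir / "fit_meta.json").read_text())
    cfg = McmcConfig(**meta["mcmc"])
    samples = PosteriorSamples.from_dataframe(pd.read_csv(fit_dir / "posterior.csv"), cfg)
    return samples, meta


def cmd_report(
    ssm_fit_dir: str | Path,
    data_dir: str | Path,
    out_dir: str | Path,
    reduced_fit_dir: str | Path | None = None,
) -> Path:
    """Headline outputs: emigration series, fold change, occupancy counts,
    and (when a reduced fit is supplied) the variant comparison."""
    ssm_fit_dir, data_dir, out = Path(ssm_fit_dir), Path(data_dir), Path(out_dir)
    inputs = _input_hashes(data_dir, _DATA_FILES)
    inputs["posterior.csv"] = _sha256(ssm_fit_dir / "posterior.csv")
    manifest = RunManifest("report", {"ssm_fit": str(ssm_fit_dir)}, 0, inputs=inputs)

    def body():
        ds = _load_dataset(data_dir)
        samples, meta = _load_ssm_fit(ssm_fit_dir)
        series = predict_emigration_series(samples, ds["covariates"])
        out.mkdir(parents=True, exist_ok=True)
        series.to_frame().to_csv(out / "emigration_series.csv", index=False)
        fc = fold_change(series, ds["storm"])
        overall = overall_emigration_summary(samples, ds["covariates"])
        counts = occupancy_counts(ds["animal_matrix"])
        counts.to_csv(out / "occupancy_counts.csv", index=False)
        summary = {
            "fold_change": fc,
            "overall_emigration": overall,
            "coefficients": {
                name: posterior_summary(samples, name)
                for name in samples.parameter_names()
                if name.startswith("beta_")
            },
        }
        if reduced_fit_dir is not None:
            red_samples, red_meta = _load_ssm_fit(Path(reduced_fit_dir))
            if red_meta["data_hash"] != meta["data_hash"]:
                raise ValueError("full and reduced fits come from different data")
            shared = [
                n for n in red_samples.parameter_names()
                if n in samples.parameter_names() and red_samples.get(n).ndim == 2
            ]
            summary["variant_comparison"] = {
                "max_abs_median_diff": max(
                    abs(posterior_summary(samples, n)["median"]
                        - posterior_summary(red_samples, n)["median"])
                    for n in shared
                ),
                "parameters": shared,
            }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))

    return _run(manifest, out, body)


def cmd_recover(
    config: ScenarioConfig,
    n_replicates: int,
    out_dir: str | Path,
    sync_mcmc: McmcConfig | None = None,
    ssm_mcmc: McmcConfig | None = None,
) -> Path:
    """Simulate-and-refit replicates; write the per-parameter recovery table."""
    out = Path(out_dir)
    manifest = RunManifest(
        "recover",
        {"n_replicates": n_replicates, **json.loads(config.model_dump_json())},
        config.seed,
    )

    def body():
        table = recovery_experiment(config, n_replicates, sync_mcmc=sync_mcmc,
                                    ssm_mcmc=ssm_mcmc)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "recovery.csv", index=False)
        agg = (
            table.groupby(["model", "parameter"])
            .agg(
                coverage=("covered", "mean"),
                mean_bias=("mean", lambda s: float(np.mean(s - table.loc[s.index, "truth"]))),
                mean_sd=("sd", "mean"),
            )
            .reset_index()
        )
        agg.to_csv(out / "recovery_summary.csv", index=False)

    return _run(manifest, out, body)
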