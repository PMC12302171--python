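"""End-to-end trial pipeline: cohort -> calibrate -> factorial -> summary.

Every artifact is reproducible from the run configuration and master seed
alone; the manifest written alongside the outputs suffices to rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

from . import __version__
from .calibration import calibrate
from .config import RunConfig, config_to_dict
from .protocol import run_factorial
from .stats import summarize_cohort
from .virtual_cohort import cohort_manifest, generate_cohort

__all__ = ["run_pipeline", "PipelineError", "calibrate_cohort"]

log = logging.getLogger("afloop")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def _cohort_seed(master_seed: int):
    import numpy as np

    return np.random.SeedSequence((int(master_seed), 997))


def calibrate_cohort(cohort, settings, *, dt: float, max_iter: int | None = None):
    """Calibrate every patient in place; returns the list of results."""
    results = []
    for p in cohort:
        targets = settings.targets_for(p.edv_target)
        res = calibrate(
            p, targets=targets, max_iter=max_iter or settings.max_iter, dt=dt
        )
        results.append(res)
        log.info(
            "calibrated %s: converged=%s EF=%.1f%% sys=%.0f dia=%.0f EDV=%.0f "
            "(%d iterations)",
            p.patient_id, res.converged, res.achieved["ef"],
            res.achieved["sys"], res.achieved["dia"], res.achieved["edv"],
            res.iterations,
        )
    return results


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Run the full in-silico trial and write all artifacts.

    Writes cohort.csv, calibration_reports.json, results.csv, summary.csv,
    summary.json and manifest.json under the output directory and returns
    the artifact paths.  Raises :class:`PipelineError` naming the failing
    stage on any error.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                log.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                timings[name] = time.perf_counter() - self_inner.t0
                log.info("stage %s: done in %.1f s", name, timings[name])

        return _Stage()

    with stage("cohort"):
        cohort = generate_cohort(
            config.n_patients, _cohort_seed(config.master_seed), config.cohort
        )
        manifest_df = cohort_manifest(cohort, config.master_seed)
        cohort_path = out / "cohort.csv"
        manifest_df.to_csv(cohort_path, index=False)
        artifacts["cohort"] = str(cohort_path)

    with stage("calibrate"):
        cal_results = calibrate_cohort(cohort, config.calibration, dt=config.dt_s)
        failed = [
            p.patient_id
            for p, r in zip(cohort, cal_results)
            if not r.converged
        ]
        if failed:
            raise RuntimeError(f"calibration failed for patients {failed}")
        reports = [
            {
                "patient_id": p.patient_id,
                "converged": r.converged,
                "iterations": r.iterations,
                "parameters": r.parameters,
                "achieved": r.achieved,
                "targets": dataclasses.asdict(r.targets),
            }
            for p, r in zip(cohort, cal_results)
        ]
        cal_path = out / "calibration_reports.json"
        cal_path.write_text(json.dumps(reports, indent=2))
        artifacts["calibration"] = str(cal_path)

    with stage("factorial"):
        results = run_factorial(cohort, config)
        results_path = out / "results.csv"
        results.to_csv(results_path, index=False)
        artifacts["results"] = str(results_path)

    with stage("summarize"):
        summary = summarize_cohort(results)
        summary_csv = out / "summary.csv"
        summary.to_csv(summary_csv, index=False)
        summary_json = out / "summary.json"
        summary_json.write_text(
            json.dumps(summary.to_dict(orient="records"), indent=2, default=float)
        )
        artifacts["summary_csv"] = str(summary_csv)
        artifacts["summary_json"] = str(summary_json)

    cfg_dict = config_to_dict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "afloop_version": __version__,
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "master_seed": config.master_seed,
        "stage_timings_s": timings,
        "artifacts": artifacts,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = str(manifest_path)
    return {"artifacts": artifacts, "cohort": cohort, "results": results,
            "summary": summary, "calibration": cal_results}
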