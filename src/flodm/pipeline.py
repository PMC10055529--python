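"""Config-driven pipeline runs: simulate → reconstruct → quantify → report.

A run is described by a :class:`RunConfig`; each stage consumes only the
declared artifacts of earlier stages from the run directory, so deleting
downstream outputs and re-running reproduces them from upstream artifacts.
The config is copied verbatim into the run directory, and every stage logs
its timing and seed.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import List, Literal, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel

from flodm import io as fio
from flodm import metrics as fmetrics
from flodm import stats as fstats
from flodm import vessels as fvessels
from flodm import velocimetry as fvel
from flodm.acquisition import AcquisitionSpec
from flodm.fluor import RoiSet, compute_dff, demultiplex, extract_roi_traces
from flodm.synthetic import (
    CohortPreset,
    default_phantom,
    get_preset,
    simulate_cohort,
)
from flodm.synthetic.cohort import traces_to_csv
from flodm.synthetic.doppler import phantom_flow_traces, render_doppler_series
from flodm.synthetic.movie import (
    make_expression_field,
    movie_dff_from_cohort,
    render_two_channel_movie,
)

log = logging.getLogger("flodm")

STAGES = ("simulate", "reconstruct", "fluor", "vessels", "metrics", "stats")


class StageError(RuntimeError):
    """A stage is missing an upstream artifact; the message names the stage
    to run."""


class RunConfig(BaseModel):
    """Fully serializable description of one pipeline run."""

    preset: str = "cocaine"
    seed: int = 1
    outdir: str = "flodm_run"
    stages: List[str] = list(STAGES)
    render_movie: bool = True
    render_doppler: bool = True
    movie_shape: Tuple[int, int] = (60, 80)
    doppler_shape: Tuple[int, int, int] = (32, 64, 64)
    doppler_voxel_um: float = 4.5
    doppler_period_min: float = 1.5
    baseline_window: Tuple[float, float] = (-10.0, 0.0)
    correlation_window: Tuple[float, float] = (0.0, 60.0)
    acquisition: AcquisitionSpec = AcquisitionSpec()

    def load_preset(self) -> CohortPreset:
        if self.preset.endswith(".json") or "/" in self.preset:
            return CohortPreset.from_json(self.preset)
        return get_preset(self.preset)


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the final report (or a
    manifest of produced artifacts when stats is disabled)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fio.write_json(outdir / "config.json", config.model_dump())
    preset = config.load_preset()
    manifest = {"stages": {}}
    report = None
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        fn = globals()[f"_stage_{stage}"]
        result = fn(config, preset, outdir)
        dt = time.perf_counter() - t0
        log.info("stage %-11s seed=%d  %.2fs", stage, config.seed, dt)
        manifest["stages"][stage] = {"seconds": round(dt, 3), "artifacts": result}
        if stage == "stats":
            report = result
    fio.write_json(outdir / "manifest.json", manifest["stages"])
    return report if report is not None else manifest


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageError(
            f"missing artifact {path.name}; run the '{producer}' stage first"
        )
    return path


def _stage_simulate(config: RunConfig, preset: CohortPreset, outdir: Path):
    traces, truth = simulate_cohort(preset, seed=config.seed)
    traces_to_csv(traces, outdir / "traces.csv")
    truth["gains"].to_csv(outdir / "ground_truth_gains.csv", index=False,
                          float_format="%.6f")
    truth["estimands"].to_csv(outdir / "ground_truth_estimands.csv", index=False,
                              float_format="%.6f")
    preset.to_json(outdir / "preset.json")
    artifacts = ["traces.csv", "ground_truth_gains.csv",
                 "ground_truth_estimands.csv", "preset.json"]

    if config.render_movie:
        field = make_expression_field(shape=config.movie_shape,
                                      seed=config.seed + 10)
        dff, times = movie_dff_from_cohort(traces, animal=1,
                                           n_rois=preset.rois_per_signal)
        frames, movie_manifest = render_two_channel_movie(
            dff, field, config.acquisition, times, seed=config.seed + 11
        )
        fio.write_stack(outdir / "movie.tif", frames, movie_manifest)
        fio.write_stack(
            outdir / "movie_labels.tif",
            np.stack([field.labels["green"], field.labels["red"]]),
            {"pages": ["green", "red"], "content": "ROI label maps"},
        )
        artifacts += ["movie.tif", "movie.json", "movie_labels.tif"]

    if config.render_doppler and preset.compartment_templates:
        phantom = default_phantom(
            shape=config.doppler_shape, voxel_um=config.doppler_voxel_um
        )
        t0, t1 = preset.window
        times = np.arange(t0, t1 + 1e-9, config.doppler_period_min)
        flow = phantom_flow_traces(preset, phantom, times)
        phases, sidecar = render_doppler_series(
            phantom, flow, config.acquisition, times, seed=config.seed + 12
        )
        sidecar["shape"] = list(phases.shape)
        fio.write_stack(outdir / "doppler_phase.tif", phases, sidecar)
        phantom.truth_records().to_csv(outdir / "phantom_truth.csv", index=False,
                                       float_format="%.6f")
        artifacts += ["doppler_phase.tif", "doppler_phase.json", "phantom_truth.csv"]
    return artifacts


def _stage_reconstruct(config: RunConfig, preset: CohortPreset, outdir: Path):
    if not (config.render_doppler and preset.compartment_templates):
        return []
    phases, sidecar = fio.read_stack(
        _require(outdir / "doppler_phase.tif", "simulate")
    )
    acq = AcquisitionSpec(**sidecar["acquisition"])
    times = np.asarray(sidecar["timestamps_min"])
    volumes = fvel.reconstruct_series(phases, times, acq,
                                      sigma_phi=sidecar["background_phase_sd"])
    ratios, valid, _ = fvel.ratio_series(
        volumes, config.baseline_window, acq=acq,
        sigma_v=fvel.velocity_sensitivity(acq, sidecar["background_phase_sd"]),
    )
    vel = np.stack([v.v_mm_s for v in volumes]).astype(np.float32)
    fio.write_stack(outdir / "velocity.tif", vel,
                    {"axis_order": "t,z,y,x", "shape": list(vel.shape),
                     "timestamps_min": times.tolist(), "units": "mm/s"})
    fio.write_stack(outdir / "cbfv_ratio.tif", ratios.astype(np.float32),
                    {"axis_order": "t,z,y,x", "shape": list(ratios.shape),
                     "timestamps_min": times.tolist(), "units": "percent"})
    return ["velocity.tif", "cbfv_ratio.tif"]


def _stage_fluor(config: RunConfig, preset: CohortPreset, outdir: Path):
    if not config.render_movie:
        return []
    frames, manifest = fio.read_stack(_require(outdir / "movie.tif", "simulate"))
    labels = fio.read_stack(
        _require(outdir / "movie_labels.tif", "simulate"), with_sidecar=False
    )
    split = demultiplex(frames, manifest)
    rows = []
    for ci, channel in enumerate(("green", "red")):
        movie = split[channel]
        dff = compute_dff(movie["frames"], movie["t_min"],
                          baseline_window=config.baseline_window)
        rois = RoiSet.from_labels(labels[ci], channel)
        tr = extract_roi_traces(dff, movie["t_min"], rois)
        rows.append(tr)
    measured = pd.concat(rows, ignore_index=True)
    traces_to_csv(measured, outdir / "measured_fluor_traces.csv")
    return ["measured_fluor_traces.csv"]


def _stage_vessels(config: RunConfig, preset: CohortPreset, outdir: Path):
    if not (config.render_doppler and preset.compartment_templates):
        return []
    vel, sidecar = fio.read_stack(_require(outdir / "velocity.tif", "reconstruct"))
    ratios, rsidecar = fio.read_stack(
        _require(outdir / "cbfv_ratio.tif", "reconstruct")
    )
    times = np.asarray(sidecar["timestamps_min"])
    acq = config.acquisition
    floor = 3 * fvel.velocity_sensitivity(acq, acq.sigma_phi_rad)
    base = (times >= config.baseline_window[0]) & (times <= config.baseline_window[1])
    baseline_vel = vel[base].mean(axis=0)
    seg = fvessels.segment_vessels(baseline_vel, voxel_um=config.doppler_voxel_um,
                                   velocity_floor=floor)
    records = fvessels.classify_compartment(seg.records)
    per_segment, per_comp = fvessels.compartment_flow_traces(
        ratios, times, seg, records
    )
    records.to_csv(outdir / "segments.csv", index=False, float_format="%.6f")
    per_segment.to_csv(outdir / "segment_flow_traces.csv", index=False,
                       float_format="%.6f")
    per_comp.to_csv(outdir / "compartment_flow_traces.csv", index=False,
                    float_format="%.6f")
    return ["segments.csv", "segment_flow_traces.csv",
            "compartment_flow_traces.csv"]


def _stage_metrics(config: RunConfig, preset: CohortPreset, outdir: Path):
    traces = pd.read_csv(_require(outdir / "traces.csv", "simulate"))
    metrics = fmetrics.compute_metrics(traces,
                                       baseline_window=config.baseline_window)
    rollup = fmetrics.group_rollup(metrics)
    metrics.to_csv(outdir / "metrics.csv", index=False, float_format="%.6f")
    rollup.to_csv(outdir / "metrics_rollup.csv", index=False, float_format="%.6f")
    return ["metrics.csv", "metrics_rollup.csv"]


def _stage_stats(config: RunConfig, preset: CohortPreset, outdir: Path):
    traces = pd.read_csv(_require(outdir / "traces.csv", "simulate"))
    metrics = pd.read_csv(_require(outdir / "metrics.csv", "metrics"))
    rollup = pd.read_csv(_require(outdir / "metrics_rollup.csv", "metrics"))
    corr = fstats.correlation_table(traces, window=config.correlation_window)
    tests = {}
    if preset.n_animals >= 3:
        piv = corr[corr.sign_convention == "flow_negated"].pivot_table(
            index="animal", columns="signal_x", values="r"
        )
        if {"Ca_A", "Ca_N"} <= set(piv.columns):
            tests["r_CaA_vs_CaN"] = fstats.paired_test(
                piv["Ca_A"].to_numpy(), piv["Ca_N"].to_numpy()
            )
    report = fstats.build_report(
        outdir,
        metrics=metrics,
        rollup=rollup,
        correlations=corr,
        config={
            "seed": config.seed,
            "preset_hash": preset.content_hash(),
            "preset_name": preset.name,
            # outdir is where the report lives, not part of the scientific
            # configuration; leaving it out keeps the content hash a pure
            # function of inputs
            "run_config": config.model_dump(exclude={"outdir"}),
        },
        tests=tests,
    )
    return report
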