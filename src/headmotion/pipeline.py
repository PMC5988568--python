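"""End-to-end orchestration: simulate -> attitude estimation -> analyses -> report.

A session mirrors the experimental structure of four five-minute foraging
trials labelled light1 - dark1 - dark2 - light2; motion-tuning classification
uses the two light trials.  All temporal parameters are stored in seconds and
bin counts derived from the sampling interval, so a non-default ``dt``
preserves the 500 ms / 1 s / 100 ms window semantics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from headmotion import ahrs, ahv, allocentric, bursts, donders, io, kinematics, synth

logger = logging.getLogger(__name__)

TRIAL_LABELS = ("light1", "dark1", "dark2", "light2")
LIGHT_TRIALS = ("light1", "light2")
COMPONENTS = ("yaw", "pitch", "roll")


@dataclass
class RunConfig:
    """Configuration of a full synthetic-session pipeline run."""

    seed: int = 0
    output_dir: str = "headmotion_run"
    trial_duration: float = 300.0
    dt: float = 0.02
    n_shuffles: int = 1000
    trial_labels: tuple[str, ...] = TRIAL_LABELS
    trajectory: dict = field(default_factory=dict)  # TrajectoryModel overrides
    neurons: list = field(default_factory=lambda: [
        {"name": "yaw_cw", "kind": "displacement_tuned", "preferred_vector": [15.0, 0.0, 0.0]},
        {"name": "pitch_down", "kind": "displacement_tuned", "preferred_vector": [0.0, -10.0, 0.0]},
        {"name": "untuned", "kind": "untuned_poisson", "baseline_rate": 5.0},
    ])
    run_ahrs_stage: bool = True
    imu_noise: dict = field(default_factory=dict)  # simulate_imu overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _simulate_trial(config: RunConfig, label: str, index: int):
    model = synth.TrajectoryModel(
        duration=config.trial_duration,
        dt=config.dt,
        seed=config.seed * 1009 + index,
        **config.trajectory,
    )
    traj, events = synth.simulate_head_trajectory(model)
    spike_trains = {}
    for j, cell_cfg in enumerate(config.neurons):
        cell_cfg = dict(cell_cfg)
        name = cell_cfg.pop("name", f"cell{j}")
        if "preferred_vector" in cell_cfg:
            cell_cfg["preferred_vector"] = tuple(cell_cfg["preferred_vector"])
        nm = synth.NeuronModel(seed=config.seed * 7919 + index * 101 + j, **cell_cfg)
        spike_trains[name] = synth.simulate_spike_train(traj, events, nm)
    return traj, events, spike_trains


def classify_cell(
    spikes_by_trial: dict[str, np.ndarray],
    traj_by_trial: dict[str, pd.DataFrame],
    trial_duration: float,
    dt: float,
    n_shuffles: int,
    seed: int,
) -> dict:
    """Motion-tuning classification of one cell from the two light trials."""
    per_component = {}
    trial_data = {}
    for li, label in enumerate(LIGHT_TRIALS):
        spikes = spikes_by_trial[label]
        cell_bursts, eligible = bursts.detect_bursts(spikes)
        trial_data[label] = (cell_bursts, eligible)
    for ci, comp in enumerate(COMPONENTS):
        per_trial = []
        for li, label in enumerate(LIGHT_TRIALS):
            cell_bursts, eligible = trial_data[label]
            angle = traj_by_trial[label][comp].to_numpy(float)
            onsets = np.array([b.onset for b in cell_bursts])
            bta = bursts.burst_triggered_average(onsets, angle, dt=dt, component=comp)
            null = bursts.shuffled_null(
                onsets,
                angle,
                trial_length=trial_duration,
                dt=dt,
                n_reps=n_shuffles,
                seed=seed + 13 * ci + li,
            ) if len(onsets) else bursts.ShuffleNull(np.array([0.0]), 0.0, 0.0, 0)
            per_trial.append((bta, null, eligible))
        result = bursts.classify_motion_tuning(
            (per_trial[0][0], per_trial[0][1]),
            (per_trial[1][0], per_trial[1][1]),
            eligible1=per_trial[0][2],
            eligible2=per_trial[1][2],
        )
        per_component[comp] = {
            "tuned": result.tuned,
            "direction": result.direction,
            "testable": result.testable,
            "mean_displacement": list(result.mean_displacements),
        }
    return per_component


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write a JSON report bundle.

    Stages: simulate the four trials (trajectory + IMU + spike trains), run
    the attitude estimator over each trial's IMU stream, detect motion events
    and fit displacement statistics, fit Donders surfaces, classify
    burst-displacement tuning across the two light trials, fit AHV models and
    allocentric tuning for each cell.  Every stage's inputs and outputs are
    serialized under ``config.output_dir``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "trials": {}, "cells": {}}

    traj_by_trial: dict[str, pd.DataFrame] = {}
    events_by_trial: dict[str, pd.DataFrame] = {}
    spikes_by_cell: dict[str, dict[str, np.ndarray]] = {}
    for index, label in enumerate(config.trial_labels):
        traj, events, spike_trains = _simulate_trial(config, label, index)
        traj_by_trial[label] = traj
        events_by_trial[label] = events
        io.write_euler(traj, out_dir / f"euler_truth_{label}.csv")
        io.write_events(events, out_dir / f"events_truth_{label}.csv")
        for name, spikes in spike_trains.items():
            spikes_by_cell.setdefault(name, {})[label] = spikes
            io.write_spikes(spikes, out_dir / f"spikes_{name}_{label}.csv")
        if config.run_ahrs_stage:
            imu = synth.simulate_imu(traj, seed=config.seed * 31 + index, **config.imu_noise)
            io.write_imu(imu, out_dir / f"imu_{label}.csv")
            est = ahrs.run_ahrs(imu)
            io.write_euler(
                est.rename(columns={"gimbal_lock": "gimbal_lock"}),
                out_dir / f"euler_est_{label}.csv",
            )
            diff = est[["yaw", "pitch", "roll"]].to_numpy() - traj[["yaw", "pitch", "roll"]].to_numpy()
            diff = (diff + 180.0) % 360.0 - 180.0  # wrap angle differences
            report["trials"].setdefault(label, {})["ahrs_rms_error_deg"] = float(
                np.sqrt(np.mean(diff**2))
            )

        # per-trial kinematics on the ground-truth trajectory
        trial_report = report["trials"].setdefault(label, {})
        for comp in COMPONENTS:
            evs = kinematics.detect_motion_events(
                traj[comp].to_numpy(float), dt=config.dt, component=comp
            )
            trial_report[f"n_events_{comp}"] = len(evs)
            if len(evs) >= 30:
                dist = kinematics.fit_displacement_distribution([e.extent for e in evs])
                trial_report[f"sigma_{comp}"] = dist.sigma
        q = donders.quat_from_euler(
            traj["yaw"].to_numpy(float), traj["pitch"].to_numpy(float), traj["roll"].to_numpy(float)
        )
        io.write_quaternions(q, out_dir / f"quaternions_{label}.csv")
        for order in ("first", "second", "fick"):
            fit = donders.fit_donders_surface(q, order=order, seed=config.seed)
            trial_report[f"tsd_{order}_deg"] = fit.tsd_deg
            if order == "fick":
                trial_report["gimbal_score"] = fit.gimbal_score

    for name, spikes_by_trial in spikes_by_cell.items():
        cell_report: dict = {}
        cell_report["motion_tuning"] = classify_cell(
            spikes_by_trial, traj_by_trial, config.trial_duration, config.dt,
            config.n_shuffles, seed=config.seed,
        )
        # AHV model selection on the first light trial, per tuned component
        traj1 = traj_by_trial[LIGHT_TRIALS[0]]
        spikes1 = spikes_by_trial[LIGHT_TRIALS[0]]
        cell_report["ahv"] = {}
        for comp in COMPONENTS:
            mt = cell_report["motion_tuning"][comp]
            direction = mt["direction"] if mt["tuned"] else None
            series = ahv.compute_ahv(traj1[comp].to_numpy(float), dt=config.dt)
            try:
                fit = ahv.fit_ahv_models(
                    series, spikes1, dt=config.dt, displacement_direction=direction
                )
                cell_report["ahv"][comp] = {
                    "delta_bic": fit.delta_bic,
                    "center": fit.skew_params.get("center", float("nan")),
                    "classified": fit.classified,
                }
            except ValueError as exc:
                cell_report["ahv"][comp] = {"error": str(exc)}
        # allocentric tuning across the two light trials
        cell_report["allocentric"] = {}
        for axis, comp in (("azimuth", "yaw"), ("elevation", "pitch"), ("bank", "roll")):
            trials = []
            for li, label in enumerate(LIGHT_TRIALS):
                heading = traj_by_trial[label][comp].to_numpy(float)
                spk = spikes_by_trial[label]
                curve = allocentric.tuning_curve(spk, heading, dt=config.dt, axis=axis)
                null = allocentric.shuffled_curves(
                    spk, heading, config.trial_duration, dt=config.dt, axis=axis,
                    n_reps=config.n_shuffles, seed=config.seed + li,
                )
                trials.append((curve, null))
            cls = allocentric.classify_allocentric_modulation(axis, trials[0], trials[1])
            cell_report["allocentric"][axis] = {
                "modulated": cls.modulated,
                "statistics": list(cls.statistics),
            }
        report["cells"][name] = cell_report

    report_path = out_dir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("pipeline report written to %s", report_path)
    return report


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh)
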