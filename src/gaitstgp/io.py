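"""Plain-text readers/writers for trials and derived tables.

A trial directory contains ``markers.csv`` (time + x/y/z per marker),
``imu_<sensor>.csv`` (time, ax, ay, az, gx, gy, gz), ``truth.json`` (events
and per-stride STGPs) and ``subject.json``.  All CSVs carry a header row, SI
units, '.' decimal separator.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from .params import STGP_NAMES
from .simulate import GaitTrial, MARKER_NAMES, SENSOR_NAMES, IMU_CHANNELS


def write_trial(trial: GaitTrial, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    cols = {"time": trial.marker_time}
    for m in MARKER_NAMES:
        for j, ax in enumerate("xyz"):
            cols[f"{m}_{ax}"] = trial.markers[m][:, j]
    pd.DataFrame(cols).to_csv(d / "markers.csv", index=False)

    for s in SENSOR_NAMES:
        df = pd.DataFrame(trial.imu[s], columns=IMU_CHANNELS)
        df.insert(0, "time", trial.imu_time)
        df.to_csv(d / f"imu_{s}.csv", index=False)

    truth = {
        "events": {
            side: {k: list(v) for k, v in ev.items()}
            for side, ev in trial.events.items()
        },
        "strides": trial.truth.to_dict(orient="records"),
    }
    (d / "truth.json").write_text(json.dumps(truth, indent=1))
    (d / "subject.json").write_text(
        json.dumps(
            {
                "subject_id": trial.subject_id,
                "cohort": trial.cohort,
                "laterality": trial.laterality,
                "pace": trial.pace,
            },
            indent=1,
        )
    )
    return d


def read_trial(directory) -> GaitTrial:
    d = Path(directory)
    mk = pd.read_csv(d / "markers.csv")
    markers: Dict[str, np.ndarray] = {
        m: mk[[f"{m}_x", f"{m}_y", f"{m}_z"]].to_numpy() for m in MARKER_NAMES
    }
    imu = {}
    imu_time = None
    for s in SENSOR_NAMES:
        df = pd.read_csv(d / f"imu_{s}.csv")
        imu_time = df["time"].to_numpy()
        imu[s] = df[IMU_CHANNELS].to_numpy()
    truth = json.loads((d / "truth.json").read_text())
    subject = json.loads((d / "subject.json").read_text())
    return GaitTrial(
        subject_id=subject["subject_id"],
        cohort=subject["cohort"],
        laterality=subject["laterality"],
        pace=subject["pace"],
        marker_time=mk["time"].to_numpy(),
        markers=markers,
        imu_time=imu_time,
        imu=imu,
        events={
            side: {k: np.asarray(v) for k, v in ev.items()}
            for side, ev in truth["events"].items()
        },
        truth=pd.DataFrame(truth["strides"], columns=["side", "stride_start_time"] + STGP_NAMES),
    )


def write_stgp(stgp: pd.DataFrame, path) -> None:
    stgp.to_csv(path, index=False)


def write_events(events, path) -> None:
    payload = {
        side: {k: list(np.asarray(v)) for k, v in ev.items()} for side, ev in events.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))
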