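"""Delimited-text and JSON round-trips for traces, FRET series, QC and results.

All on-disk formats are plain text: CSV tables for per-frame data and QC
reports, JSON for models and ground-truth manifests.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .idealize import Idealization, HmmModel
from .preprocess import FretTrace, TraceQC
from .simulate import GroundTruth, IntensityTrace, SimulationConfig


def traces_to_frame(traces: Sequence[IntensityTrace]) -> pd.DataFrame:
    parts = []
    for t in traces:
        parts.append(
            pd.DataFrame(
                {
                    "molecule_id": t.molecule_id,
                    "frame": np.arange(t.n_frames),
                    "time_s": t.time,
                    "donor": t.donor,
                    "acceptor": t.acceptor,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_traces(traces: Sequence[IntensityTrace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces(path, frame_interval: float | None = None) -> list[IntensityTrace]:
    df = pd.read_csv(path)
    out = []
    for mol, grp in df.groupby("molecule_id", sort=False):
        grp = grp.sort_values("frame")
        dt = frame_interval
        if dt is None:
            times = grp["time_s"].to_numpy()
            dt = float(times[1] - times[0]) if times.size > 1 else 0.1
        out.append(
            IntensityTrace(str(mol), dt, grp["donor"].to_numpy(), grp["acceptor"].to_numpy())
        )
    return out


def write_fret(traces: Sequence[FretTrace], path) -> None:
    parts = []
    for t in traces:
        parts.append(
            pd.DataFrame(
                {
                    "molecule_id": t.molecule_id,
                    "frame": np.arange(t.n_frames),
                    "time_s": np.arange(t.n_frames) * t.frame_interval,
                    "efret": t.efret,
                    "dark": t.dark.astype(int),
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_fret(path, frame_interval: float | None = None) -> list[FretTrace]:
    df = pd.read_csv(path)
    out = []
    for mol, grp in df.groupby("molecule_id", sort=False):
        grp = grp.sort_values("frame")
        dt = frame_interval
        if dt is None:
            times = grp["time_s"].to_numpy()
            dt = float(times[1] - times[0]) if times.size > 1 else 0.1
        out.append(
            FretTrace(
                str(mol),
                dt,
                grp["efret"].to_numpy(),
                grp["dark"].to_numpy().astype(bool),
                bleach_frame=-1,
            )
        )
    return out


def qc_report_frame(report: Sequence[TraceQC]) -> pd.DataFrame:
    rows = []
    for qc in report:
        rows.append(
            {
                "molecule_id": qc.molecule_id,
                "snr_background": qc.snr_background,
                "snr_signal": qc.snr_signal,
                "n_bleach_steps": qc.n_bleach_steps,
                "n_blinks": qc.n_blinks,
                "n_frames_above_floor": qc.n_frames_above_floor,
                "passed": qc.passed,
                "failed_criteria": ";".join(map(str, qc.failed_criteria)),
            }
        )
    return pd.DataFrame(rows)


def write_idealizations(ideals: Sequence[Idealization], traces: Sequence[FretTrace], path) -> None:
    parts = []
    for ideal, trace in zip(ideals, traces):
        parts.append(
            pd.DataFrame(
                {
                    "molecule_id": ideal.molecule_id,
                    "frame": np.arange(ideal.labels.size),
                    "state": ideal.labels,
                    "efret": trace.efret,
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def write_model(model: HmmModel, path) -> None:
    Path(path).write_text(model.to_json())


def read_model(path) -> HmmModel:
    return HmmModel.from_json(Path(path).read_text())


def write_manifest(truths: Sequence[GroundTruth], cfg: SimulationConfig, path) -> None:
    """Ground-truth manifest: the generating config plus per-trace truth."""
    payload = {
        "config": {
            k: (list(map(list, v)) if k == "transition_rates" else list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "traces": [
            {
                "molecule_id": t.molecule_id,
                "state_path": t.state_path.tolist(),
                "bleach_frame": int(t.bleach_frame),
                "blink_intervals": [list(map(int, iv)) for iv in t.blink_intervals],
            }
            for t in truths
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
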