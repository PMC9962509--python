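"""Plain-text record store: one directory per dataset, CSV signals + JSON manifest.

Layout::

    <root>/manifest.json
    <root>/<record_id>/acc_<LOC>.csv   # time_s,ap,ml,v
    <root>/<record_id>/grf.csv         # time_s,ap,ml,v
    <root>/<record_id>/events.csv      # cycle,event,sample_index,time_s (truth)

Floats are written with 9 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Dataset, EVENT_NAMES, GaitCycle, GaitRecord, LOCATIONS

__all__ = ["save_dataset", "load_dataset", "events_to_frame"]

_FLOAT_FMT = "%.9g"


def _signal_frame(x: np.ndarray, fs: float) -> pd.DataFrame:
    t = np.arange(x.shape[1]) / fs
    return pd.DataFrame({"time_s": t, "ap": x[0], "ml": x[1], "v": x[2]})


def events_to_frame(record: GaitRecord) -> pd.DataFrame:
    """Ground-truth events of one record as a tidy frame (force clock)."""
    rows = []
    for i, cyc in enumerate(record.true_events):
        for name in EVENT_NAMES:
            rows.append({
                "record_id": record.record_id, "cycle": i, "event": name,
                "sample_index": cyc[name], "time_s": cyc[name] / record.fs_grf,
            })
    return pd.DataFrame(rows)


def save_dataset(dataset: Dataset, root) -> Path:
    """Write a dataset to ``root`` (created if needed); returns the path."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": dataset.seed,
        "generation_config": dataset.generation_config,
        "records": [],
    }
    for rec in dataset.records:
        rec_dir = root / rec.record_id
        rec_dir.mkdir(exist_ok=True)
        for loc in LOCATIONS:
            _signal_frame(rec.acc[loc], rec.fs_imu).to_csv(
                rec_dir / f"acc_{loc}.csv", index=False, float_format=_FLOAT_FMT
            )
        _signal_frame(rec.grf, rec.fs_grf).to_csv(
            rec_dir / "grf.csv", index=False, float_format=_FLOAT_FMT
        )
        frame = events_to_frame(rec)
        frame.drop(columns="record_id").to_csv(
            rec_dir / "events.csv", index=False, float_format=_FLOAT_FMT
        )
        cyc_meta = [
            {"start_sample": c.start_sample, "duration": c.duration,
             "events": {k: int(v) for k, v in c.events.items()}}
            for c in rec.cycles
        ]
        manifest["records"].append({
            "record_id": rec.record_id,
            "participant_id": rec.participant_id,
            "group": rec.group,
            "speed_condition": rec.speed_condition,
            "speed_mps": rec.speed_mps,
            "body_weight": rec.body_weight,
            "fs_imu": rec.fs_imu,
            "fs_grf": rec.fs_grf,
            "duration": rec.duration,
            "cycles": cyc_meta,
        })
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return root


def load_dataset(root) -> Dataset:
    """Read a dataset previously written by :func:`save_dataset`."""
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    records = []
    for meta in manifest["records"]:
        rec_dir = root / meta["record_id"]
        acc = {}
        for loc in LOCATIONS:
            frame = pd.read_csv(rec_dir / f"acc_{loc}.csv")
            acc[loc] = frame[["ap", "ml", "v"]].to_numpy().T
        grf = pd.read_csv(rec_dir / "grf.csv")[["ap", "ml", "v"]].to_numpy().T
        cycles = []
        for c in meta["cycles"]:
            start, n = c["start_sample"], int(round(c["duration"] * meta["fs_grf"]))
            cycles.append(GaitCycle(
                grf=grf[:, start : start + n],
                events={k: int(v) for k, v in c["events"].items()},
                start_sample=start, duration=c["duration"], fs_grf=meta["fs_grf"],
            ))
        records.append(GaitRecord(
            record_id=meta["record_id"],
            participant_id=meta["participant_id"],
            group=meta["group"],
            speed_condition=meta["speed_condition"],
            speed_mps=meta["speed_mps"],
            body_weight=meta["body_weight"],
            acc=acc, grf=grf,
            fs_imu=meta["fs_imu"], fs_grf=meta["fs_grf"],
            duration=meta["duration"], cycles=cycles,
        ))
    return Dataset(
        records=records, seed=manifest["seed"],
        generation_config=manifest["generation_config"],
    )
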