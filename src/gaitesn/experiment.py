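"""Sensor-location x axis-combination sweep and its summaries.

The sweep trains and scores an echo-state-network pipeline for every
combination of five sensor locations (TS, H, MM, MFT, MK) and seven
acceleration-axis subsets (AP, ML, V and their pairs/triple) — 35 input
configurations.  For each configuration the first 70% of every record trains
the readouts (standard ridge and, for force prediction, Gaussian-kernel banks
keyed on gait temporal parameters) and the remaining 30% is scored: gait
events by millisecond MAE after peak matching, forces by body-weight-fraction
MAE in three gait-cycle zones.  Summaries report per cell the best
(location, axes) pair, its distance below the 35-configuration mean in
standard deviations, and how often each location wins.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import events as ge
from . import training as tr
from .reservoir import DEFAULT_HYPERPARAMETERS, EsnHyperparameters, build_reservoir, run_reservoir
from .synthetic import Dataset, GaitRecord, LOCATIONS, EVENT_NAMES

__all__ = [
    "AXES_COMBINATIONS",
    "InputConfiguration",
    "SweepConfig",
    "SweepResults",
    "build_input_vector",
    "split_record",
    "run_sweep",
    "summarize_best",
]

logger = logging.getLogger(__name__)

AXES_COMBINATIONS = ("AP", "ML", "V", "AP-ML", "ML-V", "AP-V", "AP-ML-V")
_AXIS_ROW = {"AP": 0, "ML": 1, "V": 2}
GRF_AXES = ("AP", "ML", "V")


@dataclass(frozen=True)
class InputConfiguration:
    """One of the 35 (sensor location, axis subset) input definitions."""

    location: str
    axes: str

    def __post_init__(self):
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.axes not in AXES_COMBINATIONS:
            raise ValueError(f"unknown axes token {self.axes!r}")

    @property
    def axis_list(self) -> list:
        return self.axes.split("-")

    @property
    def n_inputs(self) -> int:
        return 1 + len(self.axis_list)


def build_input_vector(record: GaitRecord, cfg: InputConfiguration) -> np.ndarray:
    """Input sequence u(t): constant bias row then the selected axes in order.

    Returns an (N_in, T_imu) array, e.g. axes ``"AP-V"`` yields rows
    (1, a_AP, a_V).
    """
    acc = record.acc.get(cfg.location)
    if acc is None:
        raise ValueError(f"record has no acceleration data for {cfg.location!r}")
    rows = [np.ones(acc.shape[1])]
    rows += [acc[_AXIS_ROW[name]] for name in cfg.axis_list]
    return np.vstack(rows)


@dataclass
class RecordSegment:
    """A contiguous time slice of a record on both clocks."""

    acc: dict
    grf: np.ndarray
    n_imu: int
    n_grf: int


def split_record(record: GaitRecord, train_fraction: float = 0.7) -> tuple:
    """Contiguous prefix/suffix split of one record at the same time point.

    The training segment holds the first ``round(train_fraction * T_imu)``
    accelerometer samples; the force channels are cut at the same instant on
    their own clock.  Concatenating the two segments reproduces the record.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    t_imu = next(iter(record.acc.values())).shape[1]
    n_imu = int(round(train_fraction * t_imu))
    t_split = n_imu / record.fs_imu
    n_grf = int(round(t_split * record.fs_grf))
    train = RecordSegment(
        acc={k: v[:, :n_imu] for k, v in record.acc.items()},
        grf=record.grf[:, :n_grf], n_imu=n_imu, n_grf=n_grf,
    )
    test = RecordSegment(
        acc={k: v[:, n_imu:] for k, v in record.acc.items()},
        grf=record.grf[:, n_grf:],
        n_imu=t_imu - n_imu, n_grf=record.grf.shape[1] - n_grf,
    )
    return train, test


@dataclass
class SweepConfig:
    """Settings of one sweep run."""

    locations: tuple = LOCATIONS
    axes: tuple = AXES_COMBINATIONS
    methods: tuple = (
        "standard",
        "kernel:cycle_duration",
        "kernel:stance_proportion",
        "kernel:stance_duration",
    )
    tasks: tuple = ("GED", "GRF")
    train_fraction: float = 0.7
    zones: tuple = ev.ZONES
    esn: EsnHyperparameters = DEFAULT_HYPERPARAMETERS
    washout: int = 200
    gamma: float = 1e-6
    rise_threshold: float = 20.0
    n_centers: int = 5
    relative_height_floor: float = 0.3
    pooled_groups: bool = False
    stance_end_event: str = "TO"

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        for m in self.methods:
            if m != "standard" and not (
                m.startswith("kernel:") and m.split(":", 1)[1] in tr.WEIGHTING_VARIABLES
            ):
                raise ValueError(f"unknown method token {m!r}")


@dataclass
class SweepResults:
    """Tidy MAE table plus the configuration that produced it.

    ``table`` columns: group, task, method, location, axes, metric, zone,
    mae, n_records, unmatched.  ``metric`` is the event name for GED rows and
    the force axis for GRF rows; ``zone`` is empty for GED rows.
    """

    table: pd.DataFrame
    config: SweepConfig
    errors: list = field(default_factory=list)


@dataclass
class _PreparedRecord:
    record: GaitRecord
    n_train_imu: int
    ged_target: np.ndarray  # (5, T_imu)
    grf_target: np.ndarray  # (3, T_imu)
    train_events: ge.EventSet  # IMU clock, absolute indices
    test_events: ge.EventSet  # IMU clock, shifted to test-segment origin
    train_params: ge.TemporalParameters | None


def _prepare_record(record: GaitRecord, cfg: SweepConfig) -> _PreparedRecord | None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        events_grf = ge.detect_events_from_vgrf(
            record.grf[2], record.fs_grf, cfg.rise_threshold
        )
    if len(events_grf) < 3:
        return None
    events_imu = ge.map_event_indices(events_grf, record.fs_imu)
    t_imu = next(iter(record.acc.values())).shape[1]
    grf_imu = ge.resample_to_imu_clock(record.grf, record.fs_grf, record.fs_imu)
    grf_target = ge.build_grf_target(grf_imu[:, :t_imu], record.body_weight)
    cycles = [c for c in events_imu.cycles if c["TO"] < t_imu]
    ged_target = ge.build_ged_target(ge.EventSet(cycles, record.fs_imu), t_imu)

    n_train = int(round(cfg.train_fraction * t_imu))
    train_cycles = [c for c in cycles if c["TO"] < n_train]
    # evaluation cycles must lie strictly inside the test segment: a heel
    # strike on the split boundary has no rising-edge context and cannot be
    # an interior peak of the prediction
    test_cycles = [
        {k: v - n_train for k, v in c.items()}
        for c in cycles
        if c["HS"] > n_train and c["TO"] < t_imu
    ]
    if len(train_cycles) < 2 or len(test_cycles) < 2:
        return None
    train_events = ge.EventSet(train_cycles, record.fs_imu)
    params = ge.compute_temporal_parameters(train_events, cfg.stance_end_event)
    return _PreparedRecord(
        record=record,
        n_train_imu=n_train,
        ged_target=ged_target,
        grf_target=grf_target,
        train_events=train_events,
        test_events=ge.EventSet(test_cycles, record.fs_imu),
        train_params=params,
    )


def _predicted_parameters(
    y_ged_test: np.ndarray,
    fs: float,
    peak_cfg: ev.PeakFinderConfig,
    fallback: dict,
) -> dict:
    """Temporal parameters of one test segment from predicted HS/TO peaks."""
    hs = ev.detect_predicted_events(y_ged_test[0], fs, peak_cfg)
    to = ev.detect_predicted_events(y_ged_test[4], fs, peak_cfg)
    out = dict(fallback)
    if hs.size >= 2:
        cycles = np.diff(hs) / fs
        out["cycle_duration"] = float(np.mean(cycles))
        stances = []
        for i in range(hs.size - 1):
            inside = to[(to > hs[i]) & (to < hs[i + 1])]
            if inside.size:
                stances.append((inside[0] - hs[i]) / fs)
        if stances:
            out["stance_duration"] = float(np.mean(stances))
            out["stance_proportion"] = out["stance_duration"] / out["cycle_duration"]
    return out


def run_sweep(dataset: Dataset, cfg: SweepConfig, progress: bool = False) -> SweepResults:
    """Train and score every configured (location, axes, method) combination.

    One reservoir per input size is built from ``cfg.esn`` and shared across
    configurations of equal input width, so location/axes comparisons differ
    only in their inputs.  Failures of individual configurations are recorded
    in ``SweepResults.errors`` and the sweep continues.
    """
    groups: dict = {}
    if cfg.pooled_groups:
        groups["pooled"] = list(dataset.records)
    else:
        for rec in dataset.records:
            groups.setdefault(rec.group, []).append(rec)

    reservoirs = {
        n_in: build_reservoir(cfg.esn, n_in)
        for n_in in sorted({1 + len(ax.split("-")) for ax in cfg.axes})
    }

    rows: list = []
    errors: list = []
    for group, records in groups.items():
        prepared = [p for p in (_prepare_record(r, cfg) for r in records) if p is not None]
        if not prepared:
            errors.append((group, "*", "*", "no usable records"))
            continue
        mean_cycle = float(
            np.mean([p.train_params.mean_cycle_duration for p in prepared])
        )
        peak_cfg = ev.PeakFinderConfig(
            min_peak_distance=0.7 * mean_cycle,
            relative_height_floor=cfg.relative_height_floor,
        )
        group_mean_params = {
            var: float(np.mean([p.train_params.value(var) for p in prepared]))
            for var in tr.WEIGHTING_VARIABLES
        }
        for location in cfg.locations:
            for axes in cfg.axes:
                in_cfg = InputConfiguration(location, axes)
                try:
                    rows.extend(
                        _run_configuration(
                            group, prepared, in_cfg,
                            reservoirs[in_cfg.n_inputs], cfg, peak_cfg,
                            group_mean_params,
                        )
                    )
                except Exception as exc:  # keep sweeping, record the failure
                    errors.append((group, location, axes, repr(exc)))
                    logger.warning("configuration %s/%s failed: %r", location, axes, exc)
                if progress:
                    logger.info("done %s %s/%s", group, location, axes)
    table = pd.DataFrame(
        rows,
        columns=[
            "group", "task", "method", "location", "axes",
            "metric", "zone", "mae", "n_records", "unmatched",
        ],
    )
    return SweepResults(table=table, config=cfg, errors=errors)


def _zone_label(zone: tuple) -> str:
    return f"({zone[0]:g}, {zone[1]:g})"


def _run_configuration(
    group: str,
    prepared: list,
    in_cfg: InputConfiguration,
    reservoir,
    cfg: SweepConfig,
    peak_cfg: ev.PeakFinderConfig,
    group_mean_params: dict,
) -> list:
    # channel standardization from pooled training segments
    u_raw = [build_input_vector(p.record, in_cfg) for p in prepared]
    train_concat = np.hstack([u[1:, : p.n_train_imu] for u, p in zip(u_raw, prepared)])
    mu = train_concat.mean(axis=1, keepdims=True)
    sd = train_concat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0

    states = []
    for u in u_raw:
        uz = u.copy()
        uz[1:] = (u[1:] - mu) / sd
        states.append(run_reservoir(reservoir, uz))

    w0 = cfg.washout
    train_states = [s[:, w0 : p.n_train_imu] for s, p in zip(states, prepared)]
    test_states = [s[:, p.n_train_imu :] for s, p in zip(states, prepared)]
    fs = prepared[0].record.fs_imu

    rows: list = []
    ged_readout = None
    if "GED" in cfg.tasks or "GRF" in cfg.tasks:
        ged_targets = [p.ged_target[:, w0 : p.n_train_imu] for p in prepared]
        ged_readout = tr.train_standard(train_states, ged_targets, cfg.gamma)
    ged_test_preds = [
        ged_readout.w_out @ s for s in test_states
    ] if ged_readout is not None else None

    if "GED" in cfg.tasks:
        for row_idx, name in enumerate(EVENT_NAMES):
            reports = []
            for y, p in zip(ged_test_preds, prepared):
                peaks = ev.detect_predicted_events(y[row_idx], fs, peak_cfg)
                reports.append(
                    ev.match_events(p.test_events.indices(name), peaks, fs)
                )
            res = ev.compute_event_mae(reports, name)
            rows.append((
                group, "GED", "standard", in_cfg.location, in_cfg.axes,
                name, "", res.value, res.n_records, res.unmatched,
            ))

    if "GRF" in cfg.tasks:
        grf_train = [p.grf_target[:, w0 : p.n_train_imu] for p in prepared]
        grf_test = [p.grf_target[:, p.n_train_imu :] for p in prepared]
        masks = {
            zone: [ev.zone_mask(p.test_events, zone, s.shape[1])
                   for p, s in zip(prepared, test_states)]
            for zone in cfg.zones
        }
        methods: dict = {}
        if "standard" in cfg.methods:
            std = tr.train_standard(train_states, grf_train, cfg.gamma)
            methods["standard"] = [std.w_out @ s for s in test_states]
        kernel_vars = [
            m.split(":", 1)[1] for m in cfg.methods if m.startswith("kernel:")
        ]
        if kernel_vars:
            pred_params = [
                _predicted_parameters(y, fs, peak_cfg, group_mean_params)
                for y in ged_test_preds
            ]
            for var in kernel_vars:
                trained = tr.train_kernel(
                    train_states, grf_train,
                    [p.train_params.value(var) for p in prepared],
                    var, gamma=cfg.gamma, n_centers=cfg.n_centers,
                )
                preds = [
                    tr.select_kernel(trained.bank, pp[var]) @ s
                    for pp, s in zip(pred_params, test_states)
                ]
                methods[f"kernel:{var}"] = preds
        for method, preds in methods.items():
            for zone in cfg.zones:
                res = ev.compute_grf_mae(
                    preds, grf_test, masks[zone], GRF_AXES, _zone_label(zone)
                )
                for axis in GRF_AXES:
                    r = res[axis]
                    rows.append((
                        group, "GRF", method, in_cfg.location, in_cfg.axes,
                        axis, _zone_label(zone), r.value, r.n_records, 0,
                    ))
    return rows


def summarize_best(results: SweepResults) -> dict:
    """Best configuration per cell and best-location frequencies.

    For every (group, task, method, metric, zone) cell the minimum-MAE
    (location, axes) pair is reported together with its distance below the
    cell mean in population standard deviations,
    ``(min - mean) / std`` (negative by construction; 0 with a warning when
    all MAEs in the cell are equal).  Location win frequencies are computed
    over the force cells (axis x zone x method) of each group.
    """
    table = results.table.dropna(subset=["mae"])
    if table.empty:
        raise ValueError("no scored rows to summarize")
    best_rows = []
    for key, cell in table.groupby(["group", "task", "method", "metric", "zone"]):
        if len(cell) < 2:
            continue
        maes = cell["mae"].to_numpy(dtype=float)
        idx = int(np.argmin(maes))
        std = float(np.std(maes))  # population: the cell is the full universe
        if std == 0.0:
            warnings.warn(f"degenerate cell {key}: all MAEs equal", stacklevel=2)
            dist = 0.0
        else:
            dist = (float(maes.min()) - float(maes.mean())) / std
        winner = cell.iloc[idx]
        best_rows.append({
            "group": key[0], "task": key[1], "method": key[2],
            "metric": key[3], "zone": key[4],
            "best_location": winner["location"], "best_axes": winner["axes"],
            "mae": float(winner["mae"]), "distance_sigma": dist,
            "n_configurations": int(len(cell)),
        })
    best = pd.DataFrame(best_rows)

    freq_rows = []
    grf_best = best[best["task"] == "GRF"]
    for group, cell in grf_best.groupby("group"):
        counts = cell["best_location"].value_counts()
        n_cells = len(cell)
        for loc in LOCATIONS:
            freq_rows.append({
                "group": group, "location": loc,
                "wins": int(counts.get(loc, 0)),
                "n_cells": n_cells,
                "frequency": counts.get(loc, 0) / n_cells if n_cells else math.nan,
            })
    return {"best": best, "location_frequency": pd.DataFrame(freq_rows)}
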