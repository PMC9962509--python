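"""Scoring of event and force predictions: peak matching, zoned MAE.

Event predictions are continuous readout rows; discrete events are recovered
with a minimum-separation peak finder whose distance threshold is 0.7 x the
group's mean training-set cycle duration.  Each target event is matched
one-to-one to the nearest predicted peak and errors are reported in
milliseconds.  Force predictions are scored as mean absolute error in body
weight fractions, averaged record-wise (mean over records of the per-record
mean over samples), optionally restricted to gait-cycle percentage zones —
the full cycle (0, 100), weight acceptance (10, 18) and push-off (44, 52).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "PeakFinderConfig",
    "EventMatchReport",
    "MaeResult",
    "ZONES",
    "detect_predicted_events",
    "match_events",
    "compute_event_mae",
    "zone_mask",
    "compute_grf_mae",
]

#: gait-cycle percentage windows used for force scoring
ZONES = ((0.0, 100.0), (10.0, 18.0), (44.0, 52.0))


@dataclass(frozen=True)
class PeakFinderConfig:
    """Peak-finder settings for event recovery from readout rows.

    ``min_peak_distance`` (s) is typically 0.7 x the group's mean cycle
    duration; ``relative_height_floor`` discards peaks below this fraction of
    the row maximum.
    """

    min_peak_distance: float = 1.06
    relative_height_floor: float = 0.3

    def __post_init__(self):
        if self.min_peak_distance <= 0:
            raise ValueError("min_peak_distance must be positive")
        if not 0.0 <= self.relative_height_floor < 1.0:
            raise ValueError("relative_height_floor must be in [0, 1)")


def detect_predicted_events(
    y_row: np.ndarray, fs: float, cfg: PeakFinderConfig
) -> np.ndarray:
    """Indices of local maxima above the height floor, minimum separation apart.

    When two candidates are closer than ``min_peak_distance`` the higher one
    survives.  An all-zero (or all-flat) row yields an empty array.
    """
    y = np.asarray(y_row, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("row must have at least 2 samples")
    top = y.max()
    if top <= 0:
        return np.array([], dtype=int)
    distance = max(int(round(cfg.min_peak_distance * fs)), 1)
    peaks, _ = sps.find_peaks(
        y, height=cfg.relative_height_floor * top, distance=distance
    )
    return peaks


@dataclass
class EventMatchReport:
    """Matched target/prediction times for one event type in one record."""

    pairs: list = field(default_factory=list)  # (target_idx, predicted_idx)
    errors_ms: np.ndarray = field(default_factory=lambda: np.array([]))
    unmatched_targets: int = 0

    @property
    def mae_ms(self) -> float:
        return float(np.mean(self.errors_ms)) if self.errors_ms.size else math.nan


def match_events(
    target_indices, predicted_indices, fs: float
) -> EventMatchReport:
    """One-to-one greedy matching of targets to nearest predicted peaks.

    Candidate (target, prediction) pairs are taken in order of increasing
    absolute time difference; each target and each prediction is used at most
    once.  Unmatched targets are counted and excluded from the error list.
    """
    targets = np.asarray(target_indices, dtype=int)
    preds = np.asarray(predicted_indices, dtype=int)
    if targets.size == 0:
        return EventMatchReport()
    if preds.size == 0:
        return EventMatchReport(unmatched_targets=int(targets.size))
    cand = sorted(
        ((abs(int(ti) - int(pj)), i, j)
         for i, ti in enumerate(targets) for j, pj in enumerate(preds)),
        key=lambda c: (c[0], c[1], c[2]),
    )
    used_t: set = set()
    used_p: set = set()
    pairs = []
    errors = []
    for d, i, j in cand:
        if i in used_t or j in used_p:
            continue
        used_t.add(i)
        used_p.add(j)
        pairs.append((int(targets[i]), int(preds[j])))
        errors.append(d / fs * 1000.0)
    return EventMatchReport(
        pairs=pairs,
        errors_ms=np.asarray(errors, dtype=float),
        unmatched_targets=int(targets.size - len(pairs)),
    )


@dataclass
class MaeResult:
    """A record-weighted mean absolute error with its context."""

    value: float  # ms for events, body-weight fraction for forces
    task: str
    label: str  # event name or zone label
    n_records: int
    unmatched: int = 0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def compute_event_mae(reports: list, event_name: str = "") -> MaeResult:
    """Record-weighted MAE in ms over per-record match reports.

    The outer mean runs over records and the inner mean over each record's
    matched events, so records with many cycles do not dominate.  Records
    with no matches are excluded from the mean but their unmatched targets
    are counted; if no record has a match the value is NaN.
    """
    per_record = [r.mae_ms for r in reports if r.errors_ms.size]
    unmatched = sum(r.unmatched_targets for r in reports)
    value = float(np.mean(per_record)) if per_record else math.nan
    return MaeResult(
        value=value, task="GED", label=event_name,
        n_records=len(per_record), unmatched=unmatched,
    )


def zone_mask(events, zone: tuple, t: int) -> np.ndarray:
    """Boolean mask of samples whose cycle-phase percentage lies in [lo, hi).

    Cycles span consecutive heel strikes of the (force-derived) event set;
    samples outside complete HS-to-HS cycles are always False, so (0, 100)
    covers exactly the complete cycles.
    """
    lo, hi = zone
    if not 0.0 <= lo < hi <= 100.0:
        raise ValueError("zone must satisfy 0 <= lo < hi <= 100")
    mask = np.zeros(t, dtype=bool)
    hs = events.indices("HS")
    for h0, h1 in zip(hs[:-1], hs[1:]):
        if h1 > t:
            break
        idx = np.arange(h0, min(h1, t))
        pct = 100.0 * (idx - h0) / (h1 - h0)
        mask[idx] = (pct >= lo) & (pct < hi)
    return mask


def compute_grf_mae(
    preds_per_record,
    targets_per_record,
    masks_per_record,
    axis_names=("AP", "ML", "V"),
    label: str = "",
) -> dict:
    """Per-axis record-weighted MAE of force predictions on masked samples.

    Each element of the per-record lists is a (3, T) array / length-T mask.
    Returns a dict axis -> :class:`MaeResult` in body-weight fractions;
    records with an empty mask are skipped.
    """
    per_axis: dict = {name: [] for name in axis_names}
    n_used = 0
    for pred, target, mask in zip(
        preds_per_record, targets_per_record, masks_per_record
    ):
        pred = np.asarray(pred, dtype=float)
        target = np.asarray(target, dtype=float)
        if pred.shape != target.shape:
            raise ValueError("prediction and target shapes differ")
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            continue
        n_used += 1
        err = np.abs(pred[:, mask] - target[:, mask])
        for ax, name in enumerate(axis_names):
            per_axis[name].append(float(np.mean(err[ax])))
    return {
        name: MaeResult(
            value=float(np.mean(vals)) if vals else math.nan,
            task="GRF", label=label, n_records=n_used,
        )
        for name, vals in per_axis.items()
    }
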