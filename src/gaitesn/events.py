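"""Gait-event labeling from vertical GRF, prediction targets, temporal parameters.

Five stance-phase events are defined on the measured vertical ground reaction
force: HS is the rising edge of ground contact, HP the first force maximum
after HS, FF the mid-stance minimum (or the HP-TP midpoint when the valley is
flat, as in slow/MKOA gait), TP the last force maximum before toe off, and TO
the falling edge of contact.  From labeled events this module builds the two
prediction targets — a 5-row binary event matrix and the body-weight
normalized 3-row force matrix — and the per-cycle temporal parameters (cycle
duration, stance duration, stance proportion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synthetic import EVENT_NAMES

__all__ = [
    "EventSet",
    "TemporalParameters",
    "detect_events_from_vgrf",
    "build_ged_target",
    "build_grf_target",
    "compute_temporal_parameters",
    "resample_to_imu_clock",
    "map_event_indices",
]

DEFAULT_RISE_THRESHOLD = 20.0  # N; ~3% BW for a 70 kg adult


@dataclass
class EventSet:
    """Ordered per-cycle sample indices of the five stance events.

    ``cycles`` is a list of dicts mapping event name (HS, HP, FF, TP, TO) to a
    sample index at rate ``fs``.  Within every cycle HS < HP < FF < TP < TO,
    and consecutive cycles are disjoint with strictly increasing HS.
    """

    cycles: list = field(default_factory=list)
    fs: float = 1000.0

    def __len__(self) -> int:
        return len(self.cycles)

    def indices(self, name: str) -> np.ndarray:
        return np.array([c[name] for c in self.cycles], dtype=int)

    def validate(self) -> None:
        prev_to = -1
        for cyc in self.cycles:
            idx = [cyc[name] for name in EVENT_NAMES]
            if not all(a < b for a, b in zip(idx, idx[1:])):
                raise ValueError(f"event ordering violated in cycle {cyc}")
            if idx[0] <= prev_to:
                raise ValueError("cycles overlap or are out of order")
            prev_to = idx[-1]


def detect_events_from_vgrf(
    vgrf: np.ndarray,
    fs: float,
    rise_threshold: float = DEFAULT_RISE_THRESHOLD,
) -> EventSet:
    """Label HS, HP, FF, TP, TO on a vertical GRF trace.

    Ground contact is the set of samples where the force exceeds
    ``rise_threshold``; each maximal contact run yields one cycle with
    HS = first sample of the run and TO = last sample of the run.  Within a
    run, HP is the first local force maximum, TP the last, and FF the global
    minimum strictly between them — or ``round((HP+TP)/2)`` when no strict
    interior local minimum exists (flat mid-stance valley).  Runs touching
    the record edges (incomplete stance bouts) are dropped, as are runs in
    which fewer than two distinct maxima exist.

    Parameters
    ----------
    vgrf:
        1-D non-negative force trace in newtons.
    fs:
        Sampling rate in Hz.
    rise_threshold:
        Edge-detection force level in newtons.

    Returns
    -------
    EventSet (empty, with a warning, if no complete stance bout is found).
    """
    vgrf = np.asarray(vgrf, dtype=float).ravel()
    if fs <= 0:
        raise ValueError("fs must be positive")
    if np.any(vgrf < 0):
        raise ValueError("vertical GRF must be non-negative")

    contact = vgrf > rise_threshold
    # run starts/ends of the boolean contact mask
    diff = np.diff(contact.astype(np.int8))
    starts = np.nonzero(diff == 1)[0] + 1
    ends = np.nonzero(diff == -1)[0]
    if contact.size and contact[0]:
        starts = np.concatenate([[0], starts])
    if contact.size and contact[-1]:
        ends = np.concatenate([ends, [contact.size - 1]])

    cycles = []
    for hs, to in zip(starts, ends):
        if hs == 0 or to == vgrf.size - 1:
            continue  # incomplete bout at a record edge
        seg = vgrf[hs : to + 1]
        peaks, _ = sps.find_peaks(seg)  # plateau maxima -> middle sample
        if peaks.size < 2:
            continue
        hp = int(peaks[0])
        tp = int(peaks[-1])
        interior = seg[hp + 1 : tp]
        if interior.size and _has_strict_minimum(seg, hp, tp):
            ff = hp + 1 + int(np.argmin(interior))
        else:
            # round-half-up midpoint: invariant under index translation
            ff = (hp + tp + 1) // 2
        if not hp < ff < tp:
            continue
        cycles.append(
            {"HS": int(hs), "HP": hs + hp, "FF": hs + ff, "TP": hs + tp, "TO": int(to)}
        )
    if not cycles:
        warnings.warn("no complete stance bout found in the record", stacklevel=2)
    out = EventSet(cycles=cycles, fs=fs)
    out.validate()
    return out


def _has_strict_minimum(seg: np.ndarray, hp: int, tp: int) -> bool:
    """True if any sample strictly between hp and tp is a strict local minimum."""
    inner = seg[hp : tp + 1]
    if inner.size < 3:
        return False
    mid = inner[1:-1]
    return bool(np.any((mid < inner[:-2]) & (mid < inner[2:])))


def build_ged_target(events: EventSet, t: int) -> np.ndarray:
    """Binary (5, T) event-target matrix, rows ordered (HS, HP, FF, TP, TO).

    Each labeled cycle contributes exactly one 1 per row; every other entry
    is 0.
    """
    if t < 1:
        raise ValueError("T must be >= 1")
    out = np.zeros((5, t))
    for cyc in events.cycles:
        for row, name in enumerate(EVENT_NAMES):
            idx = cyc[name]
            if idx >= t:
                raise ValueError(f"event index {idx} >= T={t}")
            out[row, idx] = 1.0
    return out


def build_grf_target(grf: np.ndarray, body_weight: float) -> np.ndarray:
    """GRF target in multiples of body weight: element-wise ``grf / W_p``.

    ``grf`` is (3, T) in newtons, rows (AP, ML, V); multiplying the output by
    ``body_weight`` recovers the input exactly.
    """
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    grf = np.asarray(grf, dtype=float)
    if grf.ndim != 2 or grf.shape[0] != 3:
        raise ValueError("grf must be a (3, T) array")
    return grf / body_weight


@dataclass
class TemporalParameters:
    """Per-cycle gait timing derived from labeled events.

    All durations in seconds; ``stance_proportion`` is stance/cycle.  Cycle i
    spans HS_i to HS_{i+1}, so n-1 cycles are timed from n labeled bouts.
    """

    cycle_durations: np.ndarray
    stance_durations: np.ndarray
    stance_proportions: np.ndarray

    @property
    def mean_cycle_duration(self) -> float:
        return float(np.mean(self.cycle_durations))

    @property
    def mean_stance_duration(self) -> float:
        return float(np.mean(self.stance_durations))

    @property
    def mean_stance_proportion(self) -> float:
        return float(np.mean(self.stance_proportions))

    def value(self, variable: str) -> float:
        """Record-mean value of one weighting variable."""
        return {
            "cycle_duration": self.mean_cycle_duration,
            "stance_duration": self.mean_stance_duration,
            "stance_proportion": self.mean_stance_proportion,
        }[variable]


def compute_temporal_parameters(
    events: EventSet, stance_end_event: str = "TO"
) -> TemporalParameters:
    """Cycle duration, stance duration and stance proportion per cycle.

    ``cycle_duration_i = (HS_{i+1} - HS_i) / fs`` and
    ``stance_duration_i = (TO_i - HS_i) / fs``.  ``stance_end_event`` may be
    set to ``"FF"`` for the alternative stance reading; the conventional
    HS-to-TO definition is the default.
    """
    if len(events) < 2:
        raise ValueError("at least 2 labeled cycles are required")
    if stance_end_event not in ("TO", "FF"):
        raise ValueError("stance_end_event must be 'TO' or 'FF'")
    hs = events.indices("HS")
    end = events.indices(stance_end_event)
    cycle = np.diff(hs) / events.fs
    stance = (end[:-1] - hs[:-1]) / events.fs
    return TemporalParameters(
        cycle_durations=cycle,
        stance_durations=stance,
        stance_proportions=stance / cycle,
    )


def resample_to_imu_clock(
    x: np.ndarray, fs_grf: float, fs_imu: float
) -> np.ndarray:
    """Anti-alias filtered decimation of force signals onto the IMU clock.

    Polyphase FIR resampling after odd-reflection boundary extension (the
    same extension ``filtfilt`` uses), which is exact for constants and
    second-order accurate for smooth signals at the record edges.
    ``fs_grf / fs_imu`` must be rational (e.g. 1000 -> 200 Hz).
    """
    if fs_grf <= 0 or fs_imu <= 0:
        raise ValueError("sampling rates must be positive")
    if fs_imu > fs_grf:
        raise ValueError("fs_imu must not exceed fs_grf")
    from fractions import Fraction

    frac = Fraction(fs_imu / fs_grf).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    was_1d = np.asarray(x).ndim == 1
    x = np.atleast_2d(np.asarray(x, dtype=float))
    t_in = x.shape[-1]
    pad = min(10 * down, t_in - 1)
    pad -= pad % down  # keep the output offset an integer number of samples
    if pad > 0:
        left = 2.0 * x[..., :1] - x[..., pad:0:-1]
        right = 2.0 * x[..., -1:] - x[..., -2 : -pad - 2 : -1]
        ext = np.concatenate([left, x, right], axis=-1)
    else:
        ext = x
    y = sps.resample_poly(ext, up, down, axis=-1)
    off = pad * up // down
    n_out = -(-t_in * up // down)  # ceil
    y = y[..., off : off + n_out]
    return y[0] if was_1d else y


def map_event_indices(events: EventSet, fs_imu: float) -> EventSet:
    """Map event indices to the IMU clock by nearest-sample rounding."""
    ratio = fs_imu / events.fs
    cycles = [
        {name: int(round(cyc[name] * ratio)) for name in EVENT_NAMES}
        for cyc in events.cycles
    ]
    out = EventSet(cycles=cycles, fs=fs_imu)
    out.validate()
    return out
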