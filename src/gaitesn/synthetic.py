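"""Seeded synthetic gait datasets: ground reaction forces and coupled IMU signals.

The generator emulates treadmill walking records for two groups — healthy
adults and individuals with medial knee osteoarthritis (MKOA) — at three
speed conditions per participant.  The vertical ground reaction force (VGRF)
of each gait cycle is composed from raised-cosine primitives so that the five
stance-phase events (heel strike HS, heel push HP, foot flat FF, toe push TP,
toe off TO) sit at construction-time sample indices that an edge/peak-based
labeler can recover exactly on noiseless data.  Tri-axial accelerations at
five lower-limb sensor locations are deterministic functions of the gait
cycle phase (GRF-coupled component + impact transients + smooth harmonics)
plus additive Gaussian noise, with location-specific shapes and
signal-to-noise so that sensor-placement comparisons are non-degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GaitProfile",
    "GaitCycle",
    "GaitRecord",
    "Dataset",
    "HEALTHY_PROFILE",
    "MKOA_PROFILE",
    "LOCATIONS",
    "EVENT_NAMES",
    "SPEED_CONDITIONS",
    "generate_gait_cycle",
    "generate_imu_signals",
    "generate_dataset",
    "draw_self_selected_speed",
]

LOCATIONS = ("TS", "H", "MM", "MFT", "MK")
EVENT_NAMES = ("HS", "HP", "FF", "TP", "TO")
SPEED_CONDITIONS = ("slow", "self_selected", "fast")

#: gravitational acceleration used to convert body mass to weight (m/s^2)
GRAVITY = 9.81

#: default rising-edge threshold shared with the event labeler (N)
DEFAULT_RISE_THRESHOLD = 20.0

# Stance-phase breakpoints as fractions of stance duration.  Chosen asymmetric
# (valley centre not midway between the peaks) so discrete extrema are unique.
_FRAC_HP = 0.22
_FRAC_FF = 0.47
_FRAC_TP = 0.78
#: relative height of the VGRF maxima when a mid-stance valley exists
_PEAK_REL = 1.15
#: shoulder half-width (fraction of stance) and bump height for the
#: flat-valley (plateau) waveform
_PLATEAU_SHOULDER = 0.10
_PLATEAU_EPS = 0.03
#: anterior-posterior braking/propulsion lobe amplitude (fraction of BW)
_AP_REL = 0.18
#: medio-lateral amplitude (fraction of BW)
_ML_REL = 0.05


@dataclass(frozen=True)
class GaitProfile:
    """Group-level generative parameters for one population.

    Parameters
    ----------
    group:
        ``"healthy"`` or ``"mkoa"``.
    mean_speed, speed_sd:
        Self-selected walking speed distribution across participants (m/s).
    cycle_duration_mean:
        Mean gait-cycle duration at self-selected speed (s).
    cycle_duration_cv:
        Coefficient of variation of cycle durations (between and within
        records).
    stance_proportion:
        Stance time as a fraction of the gait cycle, in (0, 1).
    vgrf_valley_depth:
        Depth of the mid-stance VGRF minimum as a fraction of body weight.
        ``0`` produces the flat-valley waveform seen in slow/MKOA gait
        (no interior minimum between the two force maxima).
    impact_sharpness:
        Scales the width of heel-strike acceleration transients (>0; larger
        means narrower, sharper impact peaks).
    noise_sd:
        Accelerometer noise standard deviation as a fraction of each
        channel's noiseless signal scale.
    """

    group: str = "healthy"
    mean_speed: float = 1.28
    speed_sd: float = 0.13
    cycle_duration_mean: float = 1.05
    cycle_duration_cv: float = 0.04
    stance_proportion: float = 0.62
    vgrf_valley_depth: float = 0.35
    impact_sharpness: float = 1.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.stance_proportion < 1.0:
            raise ValueError("stance_proportion must lie strictly in (0, 1)")
        if self.vgrf_valley_depth < 0:
            raise ValueError("vgrf_valley_depth must be >= 0")
        if self.cycle_duration_mean <= 0:
            raise ValueError("cycle_duration_mean must be positive")
        if self.impact_sharpness <= 0:
            raise ValueError("impact_sharpness must be positive")


HEALTHY_PROFILE = GaitProfile()
MKOA_PROFILE = GaitProfile(
    group="mkoa",
    mean_speed=0.75,
    speed_sd=0.23,
    cycle_duration_mean=1.30,
    cycle_duration_cv=0.06,
    stance_proportion=0.66,
    vgrf_valley_depth=0.0,
    impact_sharpness=0.7,
    noise_sd=0.05,
)


@dataclass(frozen=True)
class GaitCycle:
    """One generated gait cycle: its force trace and ground-truth events.

    ``grf`` is a (3, n) array (rows AP, ML, V) in newtons on the force-plate
    clock; ``events`` maps event names to sample indices local to the cycle.
    ``start_sample`` positions the cycle inside its parent record.
    """

    grf: np.ndarray
    events: dict
    start_sample: int
    duration: float
    fs_grf: float


@dataclass
class GaitRecord:
    """One continuous walking trial."""

    record_id: str
    participant_id: str
    group: str
    speed_condition: str
    speed_mps: float
    body_weight: float
    acc: dict  # location -> (3, T_imu) array, rows (AP, ML, V), m/s^2
    grf: np.ndarray  # (3, T_grf), rows (AP, ML, V), N
    fs_imu: float
    fs_grf: float
    duration: float
    cycles: list = field(default_factory=list)  # list[GaitCycle]

    @property
    def true_events(self) -> list:
        """Per-cycle ground-truth event indices on the force-plate clock.

        Only cycles whose stance fits strictly inside the record are listed;
        a final cycle truncated during ground contact has no recoverable
        falling edge and is excluded (the labeler drops it likewise).
        """
        t_grf = self.grf.shape[1]
        out = []
        for cyc in self.cycles:
            if cyc.start_sample + cyc.events["TO"] > t_grf - 2:
                continue
            out.append(
                {name: cyc.start_sample + cyc.events[name] for name in EVENT_NAMES}
            )
        return out


@dataclass
class Dataset:
    """An ordered collection of records plus its generation provenance."""

    records: list
    seed: int
    generation_config: dict

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_group(self, group: str) -> list:
        return [r for r in self.records if r.group == group]


def _raised_cosine_rise(s: np.ndarray) -> np.ndarray:
    """0 -> 1 with zero slope at both ends, for s in [0, 1]."""
    return 0.5 * (1.0 - np.cos(np.pi * s))


def _edge_rise(s: np.ndarray) -> np.ndarray:
    """0 -> 1 quarter-cosine: steep at contact, zero slope at the peak.

    Real VGRF loads quickly at heel strike; the steep edge also keeps the
    above-threshold span close to the constructed stance duration.
    """
    return np.sin(0.5 * np.pi * s)


def _vgrf_stance(profile: GaitProfile, n_st: int, body_weight: float) -> np.ndarray:
    """Vertical force over the stance samples (length ``n_st``)."""
    s = np.arange(n_st) / (n_st - 1)
    d = profile.vgrf_valley_depth
    out = np.zeros(n_st)
    if d > 0:
        peak = _PEAK_REL
        valley = peak - d
        seg = s <= _FRAC_HP
        out[seg] = peak * _edge_rise(s[seg] / _FRAC_HP)
        seg = (s > _FRAC_HP) & (s <= _FRAC_FF)
        out[seg] = peak - (peak - valley) * _raised_cosine_rise(
            (s[seg] - _FRAC_HP) / (_FRAC_FF - _FRAC_HP)
        )
        seg = (s > _FRAC_FF) & (s <= _FRAC_TP)
        out[seg] = valley + (peak - valley) * _raised_cosine_rise(
            (s[seg] - _FRAC_FF) / (_FRAC_TP - _FRAC_FF)
        )
        seg = s > _FRAC_TP
        out[seg] = peak * _edge_rise((1.0 - s[seg]) / (1.0 - _FRAC_TP))
    else:
        # Flat-valley waveform: distinct maxima at the shoulders, an exactly
        # flat plateau (no strict interior minimum) between them.
        top = 1.0 + _PLATEAU_EPS
        w = _PLATEAU_SHOULDER
        seg = s <= _FRAC_HP
        out[seg] = top * _edge_rise(s[seg] / _FRAC_HP)
        seg = (s > _FRAC_HP) & (s <= _FRAC_HP + w)
        out[seg] = 1.0 + _PLATEAU_EPS * (1.0 - _raised_cosine_rise((s[seg] - _FRAC_HP) / w))
        seg = (s > _FRAC_HP + w) & (s <= _FRAC_TP - w)
        out[seg] = 1.0
        seg = (s > _FRAC_TP - w) & (s <= _FRAC_TP)
        out[seg] = 1.0 + _PLATEAU_EPS * _raised_cosine_rise((s[seg] - (_FRAC_TP - w)) / w)
        seg = s > _FRAC_TP
        out[seg] = top * _edge_rise((1.0 - s[seg]) / (1.0 - _FRAC_TP))
    return out * body_weight


def _lobe(s: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Raised-cosine lobe supported on [lo, hi], unit peak at the midpoint."""
    out = np.zeros_like(s)
    inside = (s >= lo) & (s <= hi)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (s[inside] - lo) / (hi - lo)))
    return out


def generate_gait_cycle(
    profile: GaitProfile,
    cycle_duration: float,
    body_weight: float,
    fs: float,
    rise_threshold: float = DEFAULT_RISE_THRESHOLD,
) -> tuple:
    """Synthesize one gait cycle of tri-axial GRF with known event locations.

    Parameters
    ----------
    profile:
        Generative parameters (stance proportion, valley depth, ...).
    cycle_duration:
        Cycle length in seconds (> 0).
    body_weight:
        Participant weight in newtons.
    fs:
        Force sampling rate in Hz (> 0).
    rise_threshold:
        Force level (N) defining the HS/TO edges of ground contact; must
        match the threshold used by the downstream event labeler for exact
        truth recovery.

    Returns
    -------
    grf : (3, n) ndarray
        Rows (AP, ML, V) in newtons; V is zero throughout swing and
        non-negative everywhere.
    events : dict
        Sample indices (local to the cycle) of HS, HP, FF, TP, TO.
    """
    if cycle_duration <= 0:
        raise ValueError("cycle_duration must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")

    n = int(round(cycle_duration * fs))
    n_st = int(round(profile.stance_proportion * n))
    if n_st < 8:
        raise ValueError("cycle too short for the stance waveform at this fs")

    grf = np.zeros((3, n))
    v = _vgrf_stance(profile, n_st, body_weight)
    grf[2, :n_st] = v

    s = np.arange(n_st) / (n_st - 1)
    grf[0, :n_st] = body_weight * _AP_REL * (
        _lobe(s, 0.05, 0.50) * -1.0 + _lobe(s, 0.50, 0.95)
    )
    grf[1, :n_st] = body_weight * _ML_REL * _lobe(s, 0.05, 0.95)

    # Construction-time event locations, using the same edge threshold and
    # the same FF-fallback midpoint rule as the labeler.
    above = np.nonzero(v > rise_threshold)[0]
    if above.size == 0:
        raise ValueError("rise_threshold exceeds the generated peak force")
    hs = int(above[0])
    to = int(above[-1])
    i_ff_break = int(_FRAC_FF * (n_st - 1))
    hp = int(np.argmax(v[: i_ff_break + 1]))
    tp = i_ff_break + int(np.argmax(v[i_ff_break:]))
    if profile.vgrf_valley_depth > 0:
        ff = hp + 1 + int(np.argmin(v[hp + 1 : tp]))
    else:
        ff = (hp + tp + 1) // 2  # round-half-up midpoint, as in the labeler
    events = {"HS": hs, "HP": hp, "FF": ff, "TP": tp, "TO": to}
    order = [events[name] for name in EVENT_NAMES]
    if not all(a < b for a, b in zip(order, order[1:])):
        raise RuntimeError("constructed events violate HS<HP<FF<TP<TO")
    return grf, events


# Location-specific acceleration shape parameters.  ``gain`` couples the
# (AP, ML, V) acceleration channels to the cycle's normalized GRF curves;
# ``impact`` are heel-strike transient amplitudes in m/s^2; ``width`` the
# transient half-width in seconds; ``harm``/``phases`` shape the smooth
# oscillatory component; ``noise_gain`` multiplies the profile noise level.
# TS (top of shoe) is constructed as the planted most-informative location:
# strongest force coupling relative to its nuisance harmonics and the lowest
# relative noise (the quantity that survives per-channel standardization).
_LOCATION_PARAMS = {
    "TS": dict(gain=(5.0, 1.5, 6.0), impact=(12.0, 1.0, 9.0), width=0.030,
               harm=1.0, phases=(0.3, 1.1, 2.0), noise_gain=1.0),
    "H": dict(gain=(3.0, 1.0, 4.0), impact=(8.0, 1.5, 12.0), width=0.025,
              harm=1.6, phases=(1.0, 2.2, 0.4), noise_gain=1.8),
    "MM": dict(gain=(2.5, 0.8, 3.0), impact=(6.0, 1.0, 7.0), width=0.035,
               harm=2.0, phases=(2.0, 0.6, 1.5), noise_gain=2.4),
    "MFT": dict(gain=(2.0, 0.8, 2.5), impact=(5.0, 1.0, 5.0), width=0.045,
                harm=2.2, phases=(0.8, 1.7, 2.6), noise_gain=3.0),
    "MK": dict(gain=(1.2, 0.5, 1.5), impact=(3.0, 0.8, 3.0), width=0.060,
               harm=2.6, phases=(1.5, 0.2, 2.9), noise_gain=4.0),
}
_HARM_DECAY = (1.0, 0.5, 0.25)


def _pulse(t: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Raised-cosine pulse in time, unit peak at ``center``."""
    out = np.zeros_like(t)
    inside = np.abs(t - center) <= half_width
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * (t[inside] - center) / half_width))
    return out


def generate_imu_signals(
    cycle_sequence: list,
    profile: GaitProfile,
    location: str,
    fs_imu: float,
    rng: np.random.Generator,
    duration: float,
) -> np.ndarray:
    """Tri-axial accelerometer trace for one sensor location.

    The noiseless waveform is a deterministic function of the gait-cycle
    sequence: a GRF-coupled component (the cycle's normalized force curves
    interpolated onto the IMU clock), raised-cosine impact transients locked
    to the true HS and TO times, and low-order harmonics of the cycle phase.
    Gaussian noise with sd = ``profile.noise_sd`` x the channel's noiseless
    standard deviation is then added.

    Parameters
    ----------
    cycle_sequence:
        list of :class:`GaitCycle` with their record placement.
    location:
        One of ``TS, H, MM, MFT, MK``.
    fs_imu:
        Accelerometer sampling rate (Hz).
    rng:
        numpy Generator; consumed only for the additive noise.
    duration:
        Record duration in seconds (defines the output length).

    Returns
    -------
    (3, T_imu) ndarray of accelerations (AP, ML, V) in m/s^2.
    """
    if location not in _LOCATION_PARAMS:
        raise ValueError(f"unknown sensor location {location!r}; expected one of {LOCATIONS}")
    if fs_imu <= 0 or duration <= 0:
        raise ValueError("fs_imu and duration must be positive")

    params = _LOCATION_PARAMS[location]
    t_imu = np.arange(int(round(duration * fs_imu))) / fs_imu
    out = np.zeros((3, t_imu.size))
    width = params["width"] / profile.impact_sharpness

    for cyc in cycle_sequence:
        t0 = cyc.start_sample / cyc.fs_grf
        in_cycle = (t_imu >= t0) & (t_imu < t0 + cyc.duration)
        if not np.any(in_cycle):
            continue
        tc = t_imu[in_cycle]
        phase = (tc - t0) / cyc.duration
        bw = max(np.max(cyc.grf[2]), 1.0)
        t_cycle_grid = t0 + np.arange(cyc.grf.shape[1]) / cyc.fs_grf
        t_hs = t0 + cyc.events["HS"] / cyc.fs_grf
        t_to = t0 + cyc.events["TO"] / cyc.fs_grf
        for ax in range(3):
            curve = np.interp(tc, t_cycle_grid, cyc.grf[ax] / bw)
            coupled = params["gain"][ax] * (curve - np.mean(cyc.grf[ax]) / bw)
            impact = params["impact"][ax] * (
                _pulse(tc, t_hs, width) + 0.4 * _pulse(tc, t_to, 1.5 * width)
            )
            harmonics = sum(
                params["harm"] * _HARM_DECAY[k]
                * np.sin(2.0 * np.pi * (k + 1) * phase + params["phases"][k])
                for k in range(3)
            )
            out[ax, in_cycle] += coupled + impact + harmonics

    if profile.noise_sd > 0:
        scale = np.std(out, axis=1)
        scale[scale == 0] = 1.0
        sd = profile.noise_sd * params["noise_gain"] * scale
        out = out + rng.normal(0.0, 1.0, out.shape) * sd[:, None]
    return out


def draw_self_selected_speed(profile: GaitProfile, rng: np.random.Generator) -> float:
    """One participant's self-selected speed (m/s), truncated at 0.3 m/s."""
    return float(max(rng.normal(profile.mean_speed, profile.speed_sd), 0.3))


# Body-mass distributions (kg) per group, converted to weight via g.
_MASS_DIST = {"healthy": (73.11, 16.45), "mkoa": (80.51, 15.27)}
_SPEED_FACTOR = {"slow": 0.8, "self_selected": 1.0, "fast": 1.2}
#: cycle duration scales as speed^-0.5 (cadence and stride length both rise
#: with speed)
_DURATION_EXPONENT = 0.5


def _generate_record(
    profile: GaitProfile,
    participant_id: str,
    condition: str,
    speed_ss: float,
    base_cycle_duration: float,
    body_weight: float,
    duration: float,
    fs_imu: float,
    fs_grf: float,
    rng: np.random.Generator,
    rise_threshold: float,
) -> GaitRecord:
    factor = _SPEED_FACTOR[condition]
    speed = speed_ss * factor
    d_mean = base_cycle_duration / factor**_DURATION_EXPONENT
    cv = profile.cycle_duration_cv

    t_grf = int(round(duration * fs_grf))
    grf = np.zeros((3, t_grf))
    cycles: list = []
    start = 0
    # walk continues to the end of the recording; the final cycle is cut off
    # wherever the record ends, as in a real treadmill trial
    while start < t_grf:
        d_c = float(np.clip(rng.normal(d_mean, cv * d_mean), 0.6 * d_mean, 1.4 * d_mean))
        cyc_grf, events = generate_gait_cycle(
            profile, d_c, body_weight, fs_grf, rise_threshold=rise_threshold
        )
        n_c = cyc_grf.shape[1]
        fit = min(n_c, t_grf - start)
        grf[:, start : start + fit] = cyc_grf[:, :fit]
        cycles.append(GaitCycle(cyc_grf, events, start, d_c, fs_grf))
        start += n_c
    if sum(c.start_sample + c.grf.shape[1] <= t_grf for c in cycles) < 3:
        raise ValueError(
            f"record duration {duration} s holds fewer than 3 cycles at "
            f"cycle duration {d_mean:.2f} s"
        )

    acc = {
        loc: generate_imu_signals(cycles, profile, loc, fs_imu, rng, duration)
        for loc in LOCATIONS
    }
    return GaitRecord(
        record_id=f"{participant_id}_{condition}",
        participant_id=participant_id,
        group=profile.group,
        speed_condition=condition,
        speed_mps=speed,
        body_weight=body_weight,
        acc=acc,
        grf=grf,
        fs_imu=fs_imu,
        fs_grf=fs_grf,
        duration=duration,
        cycles=cycles,
    )


def generate_dataset(
    n_healthy: int,
    n_mkoa: int,
    speeds_per_participant: int = 3,
    duration: float = 20.0,
    profiles: tuple = (HEALTHY_PROFILE, MKOA_PROFILE),
    seed: int = 0,
    fs_imu: float = 200.0,
    fs_grf: float = 1000.0,
    rise_threshold: float = DEFAULT_RISE_THRESHOLD,
) -> Dataset:
    """Generate a full synthetic study dataset.

    Each participant receives one record per speed condition (slow = 0.8 x,
    self-selected, fast = 1.2 x their own self-selected speed), a body weight
    drawn once from the group's mass distribution, and participant-specific
    cycle durations.  Regeneration with the same seed and configuration is
    bit-identical.

    Record count = (n_healthy + n_mkoa) x speeds_per_participant, e.g.
    27 + 18 participants at 3 speeds yields 135 records.
    """
    if n_healthy < 1 or n_mkoa < 1:
        raise ValueError("participant counts must be >= 1")
    if not 1 <= speeds_per_participant <= 3:
        raise ValueError("speeds_per_participant must be 1..3")
    healthy_profile, mkoa_profile = profiles
    conditions = SPEED_CONDITIONS[:speeds_per_participant] if speeds_per_participant < 3 \
        else SPEED_CONDITIONS
    # slowest condition must still fit >= 3 cycles
    for prof in profiles:
        slowest = prof.cycle_duration_mean / _SPEED_FACTOR["slow"] ** _DURATION_EXPONENT
        if duration < 3.1 * slowest:
            raise ValueError(
                f"duration {duration} s too short for 3 cycles of the "
                f"{prof.group} profile at the slow condition"
            )

    ss = np.random.SeedSequence(seed)
    n_total = n_healthy + n_mkoa
    children = ss.spawn(n_total)
    records: list = []
    for idx in range(n_total):
        profile = healthy_profile if idx < n_healthy else mkoa_profile
        rng = np.random.default_rng(children[idx])
        speed_ss = draw_self_selected_speed(profile, rng)
        mass_mu, mass_sd = _MASS_DIST[profile.group]
        body_weight = float(max(rng.normal(mass_mu, mass_sd), 40.0) * GRAVITY)
        base_cycle = float(
            np.clip(
                rng.normal(profile.cycle_duration_mean,
                           profile.cycle_duration_cv * profile.cycle_duration_mean),
                0.7 * profile.cycle_duration_mean,
                1.3 * profile.cycle_duration_mean,
            )
        )
        pid = f"P{idx:03d}"
        for condition in conditions:
            records.append(
                _generate_record(
                    profile, pid, condition, speed_ss, base_cycle, body_weight,
                    duration, fs_imu, fs_grf, rng, rise_threshold,
                )
            )
    config = dict(
        n_healthy=n_healthy,
        n_mkoa=n_mkoa,
        speeds_per_participant=speeds_per_participant,
        duration=duration,
        fs_imu=fs_imu,
        fs_grf=fs_grf,
        rise_threshold=rise_threshold,
        profiles={p.group: vars(p).copy() for p in profiles},
    )
    return Dataset(records=records, seed=seed, generation_config=config)
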