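"""Synthetic two-foot IMU gait cohorts with analytic ground truth.

The generator emulates a two-minute walk test recorded by one 6-axis IMU per
foot: a stride-periodic signal built from smooth raised-cosine templates, a
14-m shuttle path with turns, stroke-like vs healthy-like template variants,
white sensor noise, a constant gyroscope offset, and the sensor's measurement
ranges (+-8 g, +-500 deg/s). Because every stride is analytic, the true foot
contacts, stance phases, walked distance and generative gait factors are known
exactly, which makes the generator the oracle for the event-detection, speed
and representation-learning stages.

Kinematic model per stride (foot frame of :mod:`gaitvae.core`):

* stance: foot flat and stationary; accelerometer reads (0, 0, 1) g, the
  gyroscope only its offset plus noise.
* swing of duration ``sw``: the foot advances one stride length ``L`` with a
  raised-cosine forward-velocity bump (integral exactly ``L``), lifts along a
  ``sin^2`` arc, and pitches through a raised-cosine angle profile whose peak
  angular velocity is the subject's ``swing_peak_gyro``.
* stroke-like template adds a second harmonic to the sagittal angular
  velocity and forward-velocity profiles and a stronger foot-flat impact
  transient; the healthy-like template is the smooth symmetric variant.
* turns: whenever 14 m of cumulative distance is walked, stride length is
  reduced for a 1.5-s window and the foot yaws through a net-zero burst
  during the swing phases of the turn strides (a step turn), composed with
  the pitch rotation as R = Ry(pitch) Rz(yaw).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .core import ACC_RANGE_G, GRAVITY, GYR_RANGE_DPS, ImuRecording

TURN_EVERY_M = 14.0
TURN_DURATION_S = 1.5
TURN_SPEED_FACTOR = 0.6
TURN_YAW_PEAK_DPS = 120.0
LEAD_IN_S = 0.6  # standing still before the first stride (static segment)
IMPACT_DURATION_S = 0.03
FOOT_LIFT_M = {"stroke": 0.03, "healthy": 0.05}
IMPACT_PEAK_G = {"stroke": 0.8, "healthy": 0.3}
SECOND_HARMONIC = {"stroke": 0.3, "healthy": 0.0}


@dataclass
class SubjectParams:
    """Generative gait parameters of one subject (one session)."""

    subject_id: str
    group: str  # "stroke" | "healthy"
    mean_speed: float  # m/s
    stride_time: float  # s
    stride_time_cv: float  # coefficient of variation, unitless
    swing_fraction: float  # fraction of the stride spent in swing, in (0, 1)
    asymmetry: float  # left/right stride-parameter ratio offset, [0, 1)
    swing_peak_gyro: float  # deg/s, sagittal mid-swing peak
    noise_acc_sd: float = 0.02  # g
    noise_gyro_sd: float = 1.0  # deg/s
    gyro_offset: Tuple[float, float, float] = (0.0, 0.0, 0.0)  # deg/s
    uses_aid: bool = False

    def __post_init__(self) -> None:
        if self.mean_speed <= 0:
            raise ValueError("mean_speed must be positive")
        if not 0 < self.swing_fraction < 1:
            raise ValueError("swing_fraction must lie in (0, 1)")
        if not 0 <= self.asymmetry < 1:
            raise ValueError("asymmetry must lie in [0, 1)")
        if min(self.noise_acc_sd, self.noise_gyro_sd, self.stride_time_cv) < 0:
            raise ValueError("noise SDs and stride_time_cv must be >= 0")
        if max(abs(o) for o in self.gyro_offset) > 5.0:
            raise ValueError("|gyro_offset| must be <= 5 deg/s per axis")
        if self.group not in ("stroke", "healthy"):
            raise ValueError("group must be 'stroke' or 'healthy'")


@dataclass
class GroundTruth:
    """Exact per-foot gait truth of one simulated measurement."""

    true_contacts: Dict[str, np.ndarray]
    true_stance_intervals: Dict[str, np.ndarray]
    true_distance: float
    true_mean_speed: float
    generative_factors: Dict[str, float]
    turn_intervals: Dict[str, np.ndarray]
    true_velocity_ap: Dict[str, np.ndarray] = field(default_factory=dict)
    start_offset_samples: Dict[str, int] = field(default_factory=dict)


def _harm_norm(harm: float) -> float:
    """Peak of sin(x) - harm * sin(2x) over a period (normalizes the pitch rate)."""
    x = np.linspace(0.0, 2 * np.pi, 2001)
    return float(np.max(np.abs(np.sin(x) - harm * np.sin(2 * x))))


@dataclass
class _Stride:
    t0: float
    duration: float
    length: float
    in_turn: bool


def _plan_strides(rng: np.random.Generator, start_s: float, duration: float,
                  stride_time: float, cv: float, speed: float) -> List[_Stride]:
    """Draw the stride sequence, inserting reduced-speed turn windows every 14 m."""
    strides: List[_Stride] = []
    t = start_s
    since_turn = 0.0
    turn_until = -1.0
    while True:
        st = stride_time * (1.0 + cv * float(rng.standard_normal()))
        st = max(st, 0.4)
        if t + st > duration - 0.3:  # keep a short standing tail
            break
        in_turn = t < turn_until
        length = speed * st * (TURN_SPEED_FACTOR if in_turn else 1.0)
        strides.append(_Stride(t, st, length, in_turn))
        since_turn += length
        if since_turn >= TURN_EVERY_M and not in_turn:
            turn_until = t + st + TURN_DURATION_S
            since_turn = 0.0
        t += st
    return strides


def _render_foot(params: SubjectParams, duration: float, fs: float,
                 rng: np.random.Generator, foot: str, start_s: float):
    """Render one foot's noise-free kinematics, then add sensor imperfections."""
    variant = params.group
    side = +1.0 if foot == "left" else -1.0
    sf = float(np.clip(params.swing_fraction * (1.0 + side * params.asymmetry / 2.0),
                       0.12, 0.65))
    peak = params.swing_peak_gyro * (1.0 - side * params.asymmetry / 2.0)
    harm = SECOND_HARMONIC[variant]
    lift = FOOT_LIFT_M[variant]

    strides = _plan_strides(rng, start_s, duration, params.stride_time,
                            params.stride_time_cv, params.mean_speed)
    if len(strides) < 2:
        raise ValueError("walk too short: fewer than two strides fit the duration")

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    v_ap = np.zeros(n)
    a_ap = np.zeros(n)
    a_z = np.zeros(n)  # global vertical, gravity removed, m/s^2
    theta = np.zeros(n)  # pitch, rad
    psi = np.zeros(n)  # yaw, rad (net-zero bursts during turn swings)
    theta_dot = np.zeros(n)  # pitch rate, deg/s
    psi_dot = np.zeros(n)  # yaw rate, deg/s
    pulse_g = np.zeros(n)  # impact transient on the vertical axis, g

    contacts: List[int] = []
    stance_iv: List[Tuple[int, int]] = []
    turn_iv: List[Tuple[int, int]] = []
    deg = 180.0 / math.pi
    for s in strides:
        c = int(math.ceil(s.t0 * fs - 1e-9))
        stance_end_t = s.t0 + (1.0 - sf) * s.duration
        sw = sf * s.duration
        i0 = int(math.ceil(stance_end_t * fs - 1e-9))
        i1 = min(int(math.ceil((s.t0 + s.duration) * fs - 1e-9)), n)
        contacts.append(c)
        stance_iv.append((c, i0))
        if i1 <= i0:
            continue
        tau = (t[i0:i1] - stance_end_t) / sw
        s2, c2 = np.sin(2 * np.pi * tau), np.cos(2 * np.pi * tau)
        s4, c4 = np.sin(4 * np.pi * tau), np.cos(4 * np.pi * tau)
        base = (s.length / sw) * (1.0 - c2)
        v_ap[i0:i1] = base * (1.0 + harm * s2)
        a_ap[i0:i1] = (s.length / sw) * (2 * np.pi / sw) * (
            s2 * (1.0 + harm * s2) + (1.0 - c2) * harm * c2)
        # foot lift z(tau) = lift * sin(pi tau)^2  ->  a_z = 2 pi^2 lift cos(2 pi tau)/sw^2
        a_z[i0:i1] = 2.0 * np.pi ** 2 * lift * c2 / sw ** 2
        # pitch rate = A (sin 2 pi tau - harm sin 4 pi tau), scaled so the
        # maximum equals swing_peak_gyro; the negative second harmonic keeps
        # the mid-swing zero crossing fast (no spurious quiet plateau)
        amp = peak / _harm_norm(harm)
        theta_dot[i0:i1] = amp * (s2 - harm * s4)
        theta[i0:i1] = (amp / deg) * sw * ((1.0 - c2) / (2 * np.pi)
                                           - harm * (1.0 - c4) / (4 * np.pi))
        # foot-flat impact transient at contact
        p0, p1 = c, min(c + int(IMPACT_DURATION_S * fs), n)
        if p1 > p0:
            u = np.arange(p1 - p0) / (IMPACT_DURATION_S * fs)
            pulse_g[p0:p1] += IMPACT_PEAK_G[variant] * 0.5 * (1.0 - np.cos(2 * np.pi * u))
        if s.in_turn:
            # net-zero step-turn yaw burst during the swing phase
            psi_dot[i0:i1] += TURN_YAW_PEAK_DPS * s2
            psi[i0:i1] += (TURN_YAW_PEAK_DPS / deg) * sw / (2 * np.pi) * (1.0 - c2)
            turn_iv.append((c, i1))

    # sensor frame: R = Ry(theta) Rz(psi), so the body rates measured by the
    # gyroscope are (theta_dot sin psi, theta_dot cos psi, psi_dot) and the
    # specific force maps as a_sensor = Rz(-psi) Ry(-theta) f_global
    fx = a_ap
    fz = a_z + pulse_g * GRAVITY + GRAVITY
    ct, st_ = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(psi), np.sin(psi)
    hx = ct * fx - st_ * fz
    hz = st_ * fx + ct * fz
    acc = np.column_stack([cp * hx, -sp * hx, hz]) / GRAVITY
    gyr = np.column_stack([theta_dot * sp, theta_dot * cp, psi_dot])

    truth_v = v_ap.copy()
    distance = float(np.trapezoid(truth_v, dx=1.0 / fs))

    acc = acc + rng.normal(0.0, params.noise_acc_sd, size=acc.shape)
    gyr = gyr + np.asarray(params.gyro_offset) + \
        rng.normal(0.0, params.noise_gyro_sd, size=gyr.shape)
    acc = np.clip(acc, -ACC_RANGE_G, ACC_RANGE_G)
    gyr = np.clip(gyr, -GYR_RANGE_DPS, GYR_RANGE_DPS)

    rec = ImuRecording(time=t, acc=acc, gyr=gyr, fs=fs, foot=foot,
                       subject_id=params.subject_id, group=params.group,
                       uses_aid=params.uses_aid)
    return rec, np.array(contacts), np.array(stance_iv), np.array(turn_iv), truth_v, distance


def simulate_walk(params: SubjectParams, duration: float = 120.0,
                  fs: float = 104.0, seed: int = 0):
    """Simulate one two-minute-walk measurement for both feet.

    Returns ``(left, right, truth)`` where the recordings are raw sensor
    streams (noise, gyro offset and clipping applied) and ``truth`` holds the
    noise-free contacts, stance intervals, forward-velocity series and walked
    distance. The two IMUs are unsynchronized: each foot receives an
    independent start-time jitter of up to 0.5 s; the right foot additionally
    starts half a stride later.
    """
    if duration < 2.0 * params.stride_time:
        raise ValueError("walk too short: duration must cover at least two strides")
    if duration < 10.0:
        raise ValueError("walk too short: duration must be >= 10 s")
    rng = np.random.default_rng(seed)
    jitter = {f: float(rng.uniform(0.0, 0.5)) for f in ("left", "right")}
    start = {
        "left": LEAD_IN_S + round(jitter["left"] * fs) / fs,
        "right": LEAD_IN_S + round((jitter["right"] + 0.5 * params.stride_time
                                    * (1.0 + params.asymmetry / 4.0)) * fs) / fs,
    }

    recs, contacts, stances, turns, vels, dists, offsets = {}, {}, {}, {}, {}, {}, {}
    for foot in ("left", "right"):
        foot_rng = np.random.default_rng(rng.integers(0, 2 ** 31))
        (recs[foot], contacts[foot], stances[foot], turns[foot],
         vels[foot], dists[foot]) = _render_foot(
            params, duration, fs, foot_rng, foot, start[foot])
        offsets[foot] = int(round(start[foot] * fs))

    factors = {k: v for k, v in asdict(params).items()
               if isinstance(v, (int, float)) and not isinstance(v, bool)}
    truth = GroundTruth(
        true_contacts=contacts,
        true_stance_intervals=stances,
        true_distance=dists["right"],
        true_mean_speed=dists["right"] / duration,
        generative_factors=factors,
        turn_intervals=turns,
        true_velocity_ap=vels,
        start_offset_samples=offsets,
    )
    return recs["left"], recs["right"], truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: per-group (mean, sd, low clip, high clip) of each subject-level parameter
DEFAULT_GROUP_DISTRIBUTIONS: Dict[str, Dict[str, Tuple[float, float, float, float]]] = {
    "stroke": {
        "mean_speed": (0.7, 0.3, 0.2, 1.4),
        "stride_time": (1.30, 0.15, 0.9, 1.8),
        "stride_time_cv": (0.08, 0.02, 0.01, 0.20),
        "swing_fraction": (0.35, 0.04, 0.20, 0.55),
        "asymmetry": (0.15, 0.08, 0.0, 0.40),
        "swing_peak_gyro": (250.0, 60.0, 120.0, 450.0),
    },
    "healthy": {
        "mean_speed": (1.2, 0.15, 0.8, 1.6),
        "stride_time": (1.05, 0.08, 0.8, 1.4),
        "stride_time_cv": (0.03, 0.01, 0.005, 0.10),
        "swing_fraction": (0.42, 0.03, 0.25, 0.55),
        "asymmetry": (0.02, 0.01, 0.0, 0.10),
        "swing_peak_gyro": (350.0, 40.0, 200.0, 480.0),
    },
}

#: session-to-session (test/retest) relative perturbation per parameter
DEFAULT_SESSION_REL_SD = {
    "mean_speed": 0.04,
    "stride_time": 0.02,
    "swing_peak_gyro": 0.03,
    "swing_fraction": 0.02,
}


#: cohort configuration whose between-subject variation is driven by two
#: dominant generative factors: stride time (with gait speed tied to it via a
#: fixed 0.95-m stride length, so slower cadence also means a slower, weaker
#: push-off) and the sagittal mid-swing angular-velocity peak. All other
#: parameters are held near their group means. Used to probe whether the
#: learned latent space recovers planted gait factors.
TWO_FACTOR_DISTRIBUTIONS: Dict[str, Dict[str, Tuple[float, float, float, float]]] = {
    "stroke": {
        "mean_speed": (0.7, 0.0, 0.7, 0.7),  # overridden by the tied stride length
        "stride_time": (1.35, 0.25, 0.9, 1.8),
        "stride_time_cv": (0.01, 0.002, 0.005, 0.02),
        "swing_fraction": (0.35, 0.005, 0.33, 0.37),
        "asymmetry": (0.0, 0.0, 0.0, 0.0),
        "swing_peak_gyro": (280.0, 90.0, 110.0, 470.0),
    },
    "healthy": dict(DEFAULT_GROUP_DISTRIBUTIONS["healthy"]),
}


def two_factor_cohort_spec(n_stroke: int = 26, n_healthy: int = 0,
                           sessions: Tuple[str, ...] = ("test",),
                           seed: int = 0, **kwargs) -> "CohortSpec":
    """CohortSpec for the two-dominant-factor structure-recovery setting."""
    return CohortSpec(n_stroke=n_stroke, n_healthy=n_healthy, sessions=sessions,
                      seed=seed, group_param_distributions=TWO_FACTOR_DISTRIBUTIONS,
                      tie_speed_stride_length=0.95, **kwargs)


@dataclass
class CohortSpec:
    """Structure of a simulated cohort (subjects x sessions)."""

    n_stroke: int
    n_healthy: int
    sessions: Tuple[str, ...] = ("test", "retest")
    duration: float = 120.0
    fs: float = 104.0
    seed: int = 0
    group_param_distributions: Dict[str, Dict[str, Tuple[float, float, float, float]]] = \
        field(default_factory=lambda: DEFAULT_GROUP_DISTRIBUTIONS)
    session_rel_sd: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SESSION_REL_SD))
    longitudinal_effect: Dict[str, float] = field(default_factory=lambda: {"mean_speed": 0.0, "asymmetry": 0.0})
    longitudinal_fraction: float = 1.0  # fraction of subjects receiving the effect
    noise_acc_sd: float = 0.02
    noise_gyro_sd: float = 1.0
    gyro_offset_sd: float = 1.0
    tie_speed_stride_length: float = None  # m; when set, mean_speed = L / stride_time

    def __post_init__(self) -> None:
        if self.n_stroke < 0 or self.n_healthy < 0:
            raise ValueError("subject counts must be >= 0")
        if self.fs <= 20.0:
            raise ValueError("fs must exceed 20 Hz")
        bad = set(self.sessions) - {"test", "retest", "T0", "Tend"}
        if bad:
            raise ValueError(f"unknown sessions: {sorted(bad)}")


def draw_subject_params(subject_id: str, group: str, rng: np.random.Generator,
                        spec: CohortSpec) -> SubjectParams:
    dist = spec.group_param_distributions[group]
    vals = {}
    for name, (m, sd, lo, hi) in dist.items():
        vals[name] = float(np.clip(m + sd * rng.standard_normal(), lo, hi))
    if spec.tie_speed_stride_length is not None:
        vals["mean_speed"] = spec.tie_speed_stride_length / vals["stride_time"]
    offset = tuple(np.clip(rng.normal(0.0, spec.gyro_offset_sd, 3), -3.0, 3.0))
    uses_aid = bool(group == "stroke" and rng.uniform() < 0.4)
    return SubjectParams(subject_id=subject_id, group=group,
                         noise_acc_sd=spec.noise_acc_sd,
                         noise_gyro_sd=spec.noise_gyro_sd,
                         gyro_offset=offset, uses_aid=uses_aid, **vals)


def _perturb_session(base: SubjectParams, session: str, rng: np.random.Generator,
                     spec: CohortSpec, apply_longitudinal: bool) -> SubjectParams:
    vals = asdict(base)
    vals["gyro_offset"] = tuple(vals["gyro_offset"])
    if session != spec.sessions[0]:
        for name, rel in spec.session_rel_sd.items():
            if rel > 0:
                vals[name] = vals[name] * (1.0 + rel * float(rng.standard_normal()))
    if session == "Tend" and apply_longitudinal:
        vals["mean_speed"] = max(vals["mean_speed"] + spec.longitudinal_effect.get("mean_speed", 0.0), 0.05)
        vals["asymmetry"] = float(np.clip(vals["asymmetry"] + spec.longitudinal_effect.get("asymmetry", 0.0), 0.0, 0.9))
    vals["swing_fraction"] = float(np.clip(vals["swing_fraction"], 0.15, 0.6))
    return SubjectParams(**vals)


def simulate_cohort(spec: CohortSpec):
    """Simulate all subjects and sessions of a cohort.

    Returns ``(records, manifest)``. Each record is a dict with keys
    ``subject_id, group, session, uses_aid, measurement_id, left, right,
    truth, params``. Retest/Tend sessions reuse the subject's drawn
    parameters with a small session-level perturbation, and the whole walk
    (stride realizations included) is re-rendered from a subject-level seed,
    so a cohort with zero perturbation and zero noise yields identical
    test/retest recordings.
    """
    root = np.random.SeedSequence(spec.seed)
    subj_seeds = root.spawn(spec.n_stroke + spec.n_healthy)
    records = []
    rows = []
    groups = ["stroke"] * spec.n_stroke + ["healthy"] * spec.n_healthy
    for i, (group, ss) in enumerate(zip(groups, subj_seeds)):
        sid = f"{group[:2].upper()}{i:03d}"
        rng = np.random.default_rng(ss)
        base = draw_subject_params(sid, group, rng, spec)
        walk_seed = int(rng.integers(0, 2 ** 31))  # shared across sessions
        apply_long = bool(rng.uniform() < spec.longitudinal_fraction)
        for session in spec.sessions:
            p = _perturb_session(base, session, rng, spec, apply_long)
            left, right, truth = simulate_walk(p, spec.duration, spec.fs, walk_seed)
            mid = f"{sid}_{session}"
            for rec in (left, right):
                rec.session = session
                rec.measurement_id = mid
            records.append(dict(subject_id=sid, group=group, session=session,
                                uses_aid=p.uses_aid, measurement_id=mid,
                                left=left, right=right, truth=truth, params=p))
            rows.append(dict(measurement_id=mid, subject_id=sid, group=group,
                             session=session, uses_aid=p.uses_aid,
                             true_mean_speed=truth.true_mean_speed,
                             true_distance=truth.true_distance))
    manifest = pd.DataFrame(rows)
    return records, manifest
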