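"""Synthetic gait trial generator.

Produces walking trials with three mutually consistent views of the same
underlying gait: optical-marker trajectories at 100 Hz, seven body-worn IMU
streams (3-axis free acceleration + 3-axis angular velocity) at 40 Hz, and a
ground-truth table of per-stride spatiotemporal gait parameters (STGPs).

The kinematic model is a parametric gait cycle, not full-body dynamics: per
stride a set of free parameters (stride length, stride time, stance time,
step width, toe-out angle) is drawn from the subject's distribution, footfall
positions and event times are laid out to realize them exactly, and
piecewise-smooth trajectories interpolate the footfalls.  All event times are
snapped to the 100 Hz sample grid so that an event detector operating at
sample resolution can recover them without quantisation error.  The remaining
seven STGPs (step length/time, swing, single/double support, cadence, speed)
follow from the gait identities and are recorded from the realized layout.

Lab frame: X = direction of progression, Y = medio-lateral pointing left,
Z = vertical up, meters.  Sensor frames are taken axis-aligned with the lab
frame at neutral stance (x anterior, y medio-lateral left, z up), so the
sagittal-plane angular velocity is the gyroscope y channel by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import GenerationError
from .params import (
    BETWEEN_SUBJECT_SD_FRACTION,
    PACES,
    STGP_NAMES,
    PopulationParams,
    SubjectProfile,
    default_population_params,
)

FS_MOCAP = 100.0
FS_IMU = 40.0
_DT = 1.0 / FS_MOCAP

MARKER_NAMES = ["heel_l", "heel_r", "toe_l", "toe_r", "pelvis"]
SENSOR_NAMES = ["foot_l", "foot_r", "pelvis", "shank_l", "shank_r", "thigh_l", "thigh_r"]
IMU_CHANNELS = ["ax", "ay", "az", "gx", "gy", "gz"]

#: Stride times above this are resampled so a stride always fits the
#: 212-sample fixed window with margin for boundary jitter.
_MAX_STRIDE_TIME = 2.05
_MIN_STRIDE_TIME = 0.55
_RESAMPLE_TRIES = 100

# geometry / signal-shape constants
_FOOT_LENGTH_M = 0.22
_HEEL_ARCH_M = 0.06          # heel-marker vertical arch amplitude per stride
_TOE_BUMP_M = 0.045          # toe-marker swing clearance
_HS_DROP_RAD = 0.5           # foot plantarflexion drop after heel strike
_HS_DROP_HALFWIDTH_S = 0.03
_MAX_FALL_RATE = 8.0         # rad/s cap on the terminal-swing lobe so the
                             # post-heel-strike dip stays the deepest minimum
_SWING_RISE_FRACTION = 0.35  # fraction of swing spent in the fast dorsiflexion rise


@dataclass
class GaitTrial:
    """One simulated walking trial (markers + IMUs + ground truth)."""

    subject_id: str
    cohort: str
    laterality: str
    pace: str
    marker_time: np.ndarray              # (N,) seconds, 100 Hz
    markers: Dict[str, np.ndarray]       # name -> (N, 3) meters
    imu_time: np.ndarray                 # (M,) seconds, 40 Hz
    imu: Dict[str, np.ndarray]           # sensor -> (M, 6) [ax ay az gx gy gz]
    events: Dict[str, Dict[str, np.ndarray]]  # side -> heel_strikes / toe_offs (s)
    truth: pd.DataFrame                  # side, stride_start_time, 12 STGPs


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _snap(t: float) -> float:
    """Snap a time to the 100 Hz sample grid."""
    return round(t * FS_MOCAP) / FS_MOCAP


class _StrideLayout:
    """Footfall/event bookkeeping for one side."""

    def __init__(self) -> None:
        self.hs: List[float] = []      # heel-strike times
        self.to: List[float] = []      # toe-off times, one per stride
        self.x: List[float] = []       # footfall progression positions (m)
        self.y: List[float] = []       # footfall medio-lateral positions (m)
        self.theta: List[float] = []   # signed foot yaw at footfall (deg)
        self.stride_len: List[float] = []   # realized stride lengths (m)


def _sample_clipped(rng, mean, sd, lo, hi):
    v = rng.normal(mean, sd)
    return float(min(max(v, lo), hi))


def simulate_trial(
    profile: SubjectProfile,
    pace: str,
    n_strides: int,
    seed: int,
    noise_scale: float = 0.05,
    population: Optional[Dict[Tuple[str, str], PopulationParams]] = None,
) -> GaitTrial:
    """Simulate one walking trial.

    Parameters
    ----------
    profile
        Subject identity with per-parameter z-score offsets.
    pace
        One of ``slow``, ``normal``, ``fast``.
    n_strides
        Number of full strides per side recorded in the truth table
        (two extra boundary strides are simulated for context).
    seed
        Seed for all randomness in this trial.
    noise_scale
        SD of additive Gaussian sensor noise: ``noise_scale`` rad/s on the
        gyroscopes and ``4 * noise_scale`` m/s^2 on the accelerometers.
        Marker trajectories are noise-free (they play the ground-truth role
        of an optical system whose residual error is negligible here).
    """
    if pace not in PACES:
        raise ValueError(f"unknown pace {pace!r}")
    if n_strides < 2:
        raise ValueError("n_strides must be >= 2")
    if noise_scale < 0:
        raise ValueError("noise_scale must be nonnegative")

    pop = (population or default_population_params())[(profile.cohort, pace)]
    rng = np.random.default_rng(seed)

    f = BETWEEN_SUBJECT_SD_FRACTION
    within = np.sqrt(1.0 - f * f)
    subj_mean = {
        k: pop.mean[k] + profile.offset_z.get(k, 0.0) * f * pop.sd[k]
        for k in STGP_NAMES
    }
    sd_w = {k: within * pop.sd[k] for k in STGP_NAMES}

    m = n_strides + 2  # simulated strides per side, incl. boundary context

    # --- sample the free per-stride parameters for the reference (left) side
    T = np.empty(m + 1)
    for i in range(m + 1):
        for attempt in range(_RESAMPLE_TRIES):
            t = rng.normal(subj_mean["stride_time"], sd_w["stride_time"])
            if _MIN_STRIDE_TIME <= t <= _MAX_STRIDE_TIME:
                break
        else:
            raise GenerationError("could not sample a stride time within bounds")
        T[i] = _snap(t)

    def sample_stance(t_stride):
        # swing shorter than ~0.24 s would demand foot accelerations beyond
        # the sensor range; real swing phases do not get that short either
        lo = max(0.30 * t_stride, 0.16)
        hi = min(0.80 * t_stride, t_stride - 0.24)
        s = _sample_clipped(rng, subj_mean["stance_time"], sd_w["stance_time"], lo, hi)
        return _snap(s)

    layouts = {"L": _StrideLayout(), "R": _StrideLayout()}
    sign = {"L": 1.0, "R": -1.0}

    # Left heel strikes; right heel strikes are phase-locked half a stride
    # later so the two sequences interleave without drift.
    t0 = 1.0
    hs_l = [t0]
    for i in range(m):
        hs_l.append(_snap(hs_l[-1] + T[i]))
    off_sd = 0.5 * sd_w["step_time"]
    hs_r = [_snap(hs_l[i] + max(0.3 * T[i], min(0.7 * T[i], rng.normal(0.5 * T[i], off_sd))))
            for i in range(m + 1)]
    layouts["L"].hs = hs_l
    layouts["R"].hs = hs_r

    # Footfall progression: left advances by sampled stride lengths; the
    # right footfall sits midway between the flanking left footfalls (both
    # feet traverse the same path), which keeps step length ~ half a stride
    # without cumulative drift between the feet.
    sl_l = np.empty(m)
    for i in range(m):
        sl_l[i] = max(rng.normal(subj_mean["stride_length"], sd_w["stride_length"]), 20.0) / 100.0
    x_l = np.concatenate([[0.0], np.cumsum(sl_l)])
    x_r = np.array([0.5 * (x_l[i] + x_l[i + 1]) for i in range(m)] + [x_l[m] + 0.5 * sl_l[-1]])
    layouts["L"].x = list(x_l)
    layouts["R"].x = list(x_r)
    layouts["L"].stride_len = list(np.diff(x_l))
    layouts["R"].stride_len = list(np.diff(x_r))

    for side in ("L", "R"):
        lay = layouts[side]
        for i in range(m + 1):
            w = max(rng.normal(subj_mean["step_width"], sd_w["step_width"]), 2.0) / 100.0
            lay.y.append(sign[side] * 0.5 * w)
            lay.theta.append(rng.normal(subj_mean["toe_out_angle"], sd_w["toe_out_angle"]))
        for i in range(len(lay.hs) - 1):
            t_stride = lay.hs[i + 1] - lay.hs[i]
            lay.to.append(_snap(lay.hs[i] + sample_stance(t_stride)))

    t_end = max(layouts["L"].hs[-1], layouts["R"].hs[-1]) + 1.0

    # --- marker block (100 Hz)
    n_mk = int(np.floor(t_end * FS_MOCAP)) + 1
    t_mk = np.arange(n_mk) / FS_MOCAP
    markers = {}
    for side in ("L", "R"):
        heel, toe = _foot_marker_tracks(layouts[side], t_mk)
        markers[f"heel_{side.lower()}"] = heel
        markers[f"toe_{side.lower()}"] = toe
    pel = np.zeros((n_mk, 3))
    pel[:, 0] = 0.5 * (markers["heel_l"][:, 0] + markers["heel_r"][:, 0])
    step_period = max(subj_mean["stride_time"] / 2.0, 0.3)
    pel[:, 2] = 0.95 + 0.012 * np.cos(2.0 * np.pi * t_mk / step_period)
    markers["pelvis"] = pel

    # --- IMU block: dense 400 Hz evaluation, numerical differentiation,
    # decimation to the native 40 Hz grid, additive noise.
    fs_dense = 400.0
    n_imu = int(np.floor(t_end * FS_IMU)) + 1
    imu_t = np.arange(n_imu) / FS_IMU
    n_d = (n_imu - 1) * int(fs_dense / FS_IMU) + 1
    t_d = np.arange(n_d) / fs_dense
    pick = (np.arange(n_imu) * int(fs_dense / FS_IMU))

    dense = {}
    heel_d = {}
    for side in ("L", "R"):
        heel, _toe = _foot_marker_tracks(layouts[side], t_d)
        heel_d[side] = heel
    pel_d = np.zeros((n_d, 3))
    pel_d[:, 0] = 0.5 * (heel_d["L"][:, 0] + heel_d["R"][:, 0])
    pel_d[:, 1] = 0.02 * np.sin(2.0 * np.pi * t_d / (2.0 * step_period))
    pel_d[:, 2] = 0.95 + 0.012 * np.cos(2.0 * np.pi * t_d / step_period)

    for side in ("L", "R"):
        lay = layouts[side]
        s = sign[side]
        theta_f = _foot_pitch(lay, t_d)
        gy_f = np.gradient(theta_f, 1.0 / fs_dense)
        yaw = _foot_yaw(lay, t_d) * s
        gz_f = np.gradient(yaw, 1.0 / fs_dense)
        gx_f = s * 0.1 * gy_f
        acc_f = _second_derivative(heel_d[side], fs_dense)
        dense[f"foot_{side.lower()}"] = np.column_stack(
            [acc_f[:, 0], acc_f[:, 1], acc_f[:, 2], gx_f, gy_f, gz_f]
        )

        alpha = _shank_pitch(lay, t_d)
        gy_s = np.gradient(alpha, 1.0 / fs_dense)
        pos_s = 0.7 * heel_d[side] + 0.3 * pel_d
        acc_s = _second_derivative(pos_s, fs_dense)
        dense[f"shank_{side.lower()}"] = np.column_stack(
            [acc_s[:, 0], acc_s[:, 1], acc_s[:, 2], s * 0.15 * gy_s, gy_s, s * 0.2 * gy_s]
        )

        beta = _thigh_pitch(lay, t_d)
        gy_t = np.gradient(beta, 1.0 / fs_dense)
        pos_t = 0.35 * heel_d[side] + 0.65 * pel_d
        acc_t = _second_derivative(pos_t, fs_dense)
        dense[f"thigh_{side.lower()}"] = np.column_stack(
            [acc_t[:, 0], acc_t[:, 1], acc_t[:, 2], s * 0.15 * gy_t, gy_t, s * 0.2 * gy_t]
        )

    acc_p = _second_derivative(pel_d, fs_dense)
    phase = 2.0 * np.pi * t_d / (2.0 * step_period)
    dense["pelvis"] = np.column_stack(
        [
            acc_p[:, 0],
            acc_p[:, 1],
            acc_p[:, 2],
            0.06 * np.sin(phase),
            0.10 * np.cos(2.0 * phase),
            0.12 * np.sin(phase + 0.5),
        ]
    )

    imu = {}
    for sensor in SENSOR_NAMES:
        sig = dense[sensor][pick]
        noise = np.column_stack(
            [
                rng.normal(0.0, 4.0 * noise_scale, n_imu) if ch.startswith("a")
                else rng.normal(0.0, noise_scale, n_imu)
                for ch in IMU_CHANNELS
            ]
        ) if noise_scale > 0 else 0.0
        imu[sensor] = sig + noise

    events = {
        side: {
            "heel_strikes": np.asarray(layouts[side].hs),
            "toe_offs": np.asarray(layouts[side].to),
        }
        for side in ("L", "R")
    }

    truth = _truth_table(layouts, n_strides)

    return GaitTrial(
        subject_id=profile.subject_id,
        cohort=profile.cohort,
        laterality=profile.laterality,
        pace=pace,
        marker_time=t_mk,
        markers=markers,
        imu_time=imu_t,
        imu=imu,
        events=events,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# trajectory primitives


def _foot_marker_tracks(lay: _StrideLayout, t: np.ndarray):
    """Heel and toe marker trajectories for one side on an arbitrary grid.

    Heel X/Y hold the footfall value through stance and move to the next
    footfall during swing with zero end-point velocity, so the position read
    at a heel-strike sample equals the footfall value exactly.  Heel Z is a
    cosine arch with its minimum exactly at each heel strike.  The toe Z
    clearance bump is placed so the maximum upward toe velocity occurs
    exactly at the toe-off sample.
    """
    n = len(t)
    hs = lay.hs
    heel = np.zeros((n, 3))
    toe = np.zeros((n, 3))

    # X / Y: stance plateaus + swing smoothstep transitions
    for axis, vals in ((0, lay.x), (1, lay.y)):
        track = np.full(n, vals[0], dtype=float)
        for i in range(len(hs) - 1):
            t_to = lay.to[i]
            sl_stance = (t >= hs[i]) & (t < t_to)
            track[sl_stance] = vals[i]
            sl_swing = (t >= t_to) & (t < hs[i + 1])
            u = (t[sl_swing] - t_to) / (hs[i + 1] - t_to)
            track[sl_swing] = vals[i] + (vals[i + 1] - vals[i]) * _smoothstep(u)
        track[t >= hs[-1]] = vals[len(hs) - 1]
        heel[:, axis] = track

    # Z: per-stride cosine arch, min exactly at heel strikes; virtual
    # strides extend the pattern into the lead-in and lead-out.
    bounds = [hs[0] - 1.0] + list(hs) + [hs[-1] + 1.0]
    z = np.zeros(n)
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        sl = (t >= a) & (t < b)
        u = (t[sl] - a) / (b - a)
        z[sl] = 0.5 * _HEEL_ARCH_M * (1.0 - np.cos(2.0 * np.pi * u))
    heel[:, 2] = z

    # Toe XY: heel + foot-axis offset, orientation interpolated over swing
    th = np.radians(np.asarray(lay.theta))
    side_sign = 1.0 if lay.y[0] >= 0 else -1.0
    axis_x = _FOOT_LENGTH_M * np.cos(th)
    axis_y = _FOOT_LENGTH_M * side_sign * np.sin(th)
    for axis, vals in ((0, axis_x), (1, axis_y)):
        track = np.full(n, vals[0], dtype=float)
        for i in range(len(hs) - 1):
            t_to = lay.to[i]
            track[(t >= hs[i]) & (t < t_to)] = vals[i]
            sl_swing = (t >= t_to) & (t < hs[i + 1])
            u = (t[sl_swing] - t_to) / (hs[i + 1] - t_to)
            track[sl_swing] = vals[i] + (vals[i + 1] - vals[i]) * _smoothstep(u)
        track[t >= hs[-1]] = vals[len(hs) - 1]
        toe[:, axis] = heel[:, axis] + track

    # Toe Z: sin^2 clearance bump spanning [TO - D/4, TO + 3D/4] with D a
    # multiple of 4 samples, so the velocity peak (~ sin(2*pi*u), maximal at
    # u = 1/4) falls exactly on the toe-off sample.
    zt = np.zeros(n)
    for i in range(len(hs) - 1):
        swing = hs[i + 1] - lay.to[i]
        d_samp = max(4 * int(np.floor(swing * FS_MOCAP / 4.0)), 8)
        d = d_samp * _DT
        t_start = lay.to[i] - 0.25 * d
        sl = (t >= t_start) & (t <= t_start + d)
        u = (t[sl] - t_start) / d
        zt[sl] = np.maximum(zt[sl], _TOE_BUMP_M * np.sin(np.pi * u) ** 2)
    toe[:, 2] = zt

    return heel, toe


def _foot_pitch(lay: _StrideLayout, t: np.ndarray) -> np.ndarray:
    """Sagittal foot angle: post-heel-strike plantarflexion drop (rate
    minimum exactly at heel strike), slow stance recovery, and a swing
    dorsiflexion bump whose rise rate scales with stride length."""
    theta = np.zeros(len(t))
    w = _HS_DROP_HALFWIDTH_S
    hs = lay.hs
    for i, t_hs in enumerate(hs):
        if i >= len(lay.to):
            continue  # no recovery segment after the final strike: stay flat
        sl = (t >= t_hs - w) & (t < t_hs + w)
        theta[sl] = -_HS_DROP_RAD * _smoothstep((t[sl] - (t_hs - w)) / (2 * w))
        if i < len(lay.to):
            t_to = lay.to[i]
            sl = (t >= t_hs + w) & (t < t_to)
            u = (t[sl] - (t_hs + w)) / max(t_to - t_hs - w, 1e-6)
            theta[sl] = -_HS_DROP_RAD * (1.0 - _smoothstep(u))
            # swing bump up to the start of the next drop
            t_next = hs[i + 1] if i + 1 < len(hs) else None
            if t_next is not None:
                dur = t_next - w - t_to
                # dorsiflexion rises quickly after toe-off whatever the swing
                # duration, so the swing peak stays detectable even for slow,
                # short-stride gait
                r = min(_SWING_RISE_FRACTION * dur, 0.18)
                amp = float(np.clip(0.9 * lay.stride_len[i] / 1.2, 0.45, 1.2))
                # cap so the terminal-swing rate never out-dips the HS drop
                amp = min(amp, _MAX_FALL_RATE * (dur - r) / 1.5)
                sl_r = (t >= t_to) & (t < t_to + r)
                theta[sl_r] = amp * _smoothstep((t[sl_r] - t_to) / r)
                sl_f = (t >= t_to + r) & (t < t_next - w)
                u = (t[sl_f] - (t_to + r)) / max(dur - r, 1e-6)
                theta[sl_f] = amp * (1.0 - _smoothstep(u))
    return theta


def _foot_yaw(lay: _StrideLayout, t: np.ndarray) -> np.ndarray:
    """Unsigned in-plane foot orientation (radians), constant in stance."""
    th = np.radians(np.abs(np.asarray(lay.theta)))
    yaw = np.full(len(t), th[0])
    hs = lay.hs
    for i in range(len(hs) - 1):
        yaw[(t >= hs[i]) & (t < lay.to[i])] = th[i]
        sl = (t >= lay.to[i]) & (t < hs[i + 1])
        u = (t[sl] - lay.to[i]) / (hs[i + 1] - lay.to[i])
        yaw[sl] = th[i] + (th[i + 1] - th[i]) * _smoothstep(u)
    yaw[t >= hs[-1]] = th[len(hs) - 1]
    return yaw


def _shank_pitch(lay: _StrideLayout, t: np.ndarray) -> np.ndarray:
    # hold the stance-entry angle outside the strides (continuity at the
    # trial boundaries keeps the differentiated rates spike-free)
    alpha = np.full(len(t), -0.25)
    hs = lay.hs
    for i in range(len(hs) - 1):
        t_to = lay.to[i]
        sl = (t >= hs[i]) & (t < t_to)
        u = (t[sl] - hs[i]) / (t_to - hs[i])
        alpha[sl] = -0.25 + 0.60 * _smoothstep(u)
        sl = (t >= t_to) & (t < hs[i + 1])
        u = (t[sl] - t_to) / (hs[i + 1] - t_to)
        amp = float(np.clip(0.9 * lay.stride_len[i] / 1.2, 0.4, 1.2))
        alpha[sl] = 0.35 - 0.60 * _smoothstep(u) - 0.45 * amp * np.sin(np.pi * u) ** 2
    return alpha


def _thigh_pitch(lay: _StrideLayout, t: np.ndarray) -> np.ndarray:
    beta = np.full(len(t), 0.30)
    hs = lay.hs
    for i in range(len(hs) - 1):
        t_to = lay.to[i]
        sl = (t >= hs[i]) & (t < t_to)
        u = (t[sl] - hs[i]) / (t_to - hs[i])
        beta[sl] = 0.30 - 0.45 * _smoothstep(u)
        sl = (t >= t_to) & (t < hs[i + 1])
        u = (t[sl] - t_to) / (hs[i + 1] - t_to)
        beta[sl] = -0.15 + 0.45 * _smoothstep(u)
    return beta


def _second_derivative(pos: np.ndarray, fs: float) -> np.ndarray:
    dt = 1.0 / fs
    vel = np.gradient(pos, dt, axis=0)
    return np.gradient(vel, dt, axis=0)


# ---------------------------------------------------------------------------
# ground truth


def _truth_table(layouts: Dict[str, _StrideLayout], n_strides: int) -> pd.DataFrame:
    rows = []
    for side in ("L", "R"):
        lay = layouts[side]
        contra = layouts["R" if side == "L" else "L"]
        count = 0
        for i in range(len(lay.hs) - 1):
            if count >= n_strides:
                break
            row = _truth_stride(lay, contra, i, side)
            if row is not None:
                rows.append(row)
                count += 1
        if count < n_strides:
            raise GenerationError(
                f"only {count} of {n_strides} strides had full contralateral context"
            )
    df = pd.DataFrame(rows, columns=["side", "stride_start_time"] + STGP_NAMES)
    return df.sort_values(["side", "stride_start_time"]).reset_index(drop=True)


def _truth_stride(lay, contra, i, side):
    t_start, t_end = lay.hs[i], lay.hs[i + 1]
    tt = t_end - t_start
    # the single contralateral heel strike inside the stride
    js = [j for j, h in enumerate(contra.hs) if t_start < h < t_end]
    if len(js) != 1:
        return None
    j = js[0]
    # contralateral swing overlapping the ipsilateral stance phase
    t_to = lay.to[i]
    stance = t_to - t_start
    single = 0.0
    found_swing = False
    for k in range(len(contra.to)):
        sw_a, sw_b = contra.to[k], contra.hs[k + 1]
        ov = min(sw_b, t_to) - max(sw_a, t_start)
        if ov > 0:
            single += ov
            found_swing = True
    if not found_swing:
        return None
    single = min(single, stance)
    sl_cm = lay.stride_len[i] * 100.0
    return {
        "side": side,
        "stride_start_time": t_start,
        "step_length": (lay.x[i + 1] - contra.x[j]) * 100.0,
        "stride_length": sl_cm,
        "step_width": abs(lay.y[i + 1] - contra.y[j]) * 100.0,
        "toe_out_angle": abs(lay.theta[i]),
        "step_time": t_end - contra.hs[j],
        "stride_time": tt,
        "stance_time": stance,
        "swing_time": tt - stance,
        "single_support_time": single,
        "double_support_time": stance - single,
        "cadence": 2.0 / tt,
        "speed": sl_cm / tt,
    }
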