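"""IMU preprocessing: upsampling, stride segmentation, normalization,
fixed-length windowing and labeling.

Raw 40 Hz streams are linearly up-sampled to 100 Hz, cut into strides at the
foot's sagittal angular-velocity swing peaks (window boundaries at the signal
minimum between consecutive peaks, which for walking coincides with the
post-heel-strike deceleration dip), mirrored for left strides so both sides
share one anatomical convention, scaled into [-1, 1] by the full-scale sensor
ranges, zero-padded to 212 samples, and labeled with the marker-derived STGPs
of the matching stride.

Channel layout is fixed: sensors in the order foot-L, foot-R, pelvis,
shank-L, shank-R, thigh-L, thigh-R (restricted to the selected sensors, same
order), each contributing [ax, ay, az, gx, gy, gz].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import FormatError, SegmentationError
from .params import STGP_NAMES

logger = logging.getLogger(__name__)

TARGET_LENGTH = 212
DEFAULT_ACC_RANGE = 160.0    # m/s^2, full scale
DEFAULT_GYRO_RANGE = 34.9    # rad/s (2000 deg/s full scale)
DEFAULT_MIN_PEAK = 3.0       # rad/s, swing-peak detection threshold
DEFAULT_MIN_SEPARATION = 0.4  # s
DEFAULT_LABEL_TOLERANCE = 0.1  # s

#: canonical sensor stacking order (grouped F, P, S, T)
SENSOR_ORDER = ["foot_l", "foot_r", "pelvis", "shank_l", "shank_r", "thigh_l", "thigh_r"]
SENSOR_GROUPS = {
    "F": ["foot_l", "foot_r"],
    "P": ["pelvis"],
    "S": ["shank_l", "shank_r"],
    "T": ["thigh_l", "thigh_r"],
}


def resample_to_100hz(time: np.ndarray, data: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of a uniformly sampled stream onto a 100 Hz grid.

    The output grid spans ``[t0, tN]`` inclusive with timestamps at exact
    multiples of 0.01 s offset from ``t0``.
    """
    t = np.asarray(time, dtype=float)
    x = np.atleast_2d(np.asarray(data, dtype=float))
    if x.shape[0] == len(t):
        x = x.T  # accept (n, channels) as well as (channels, n)
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    steps = np.diff(t)
    if np.any(np.abs(steps - np.mean(steps)) > 0.01 * np.mean(steps)):
        raise FormatError("input timestamps are not uniform (jitter > 1%)")
    n_out = int(np.floor((t[-1] - t[0]) * 100.0 + 0.5 * 1e-6)) + 1
    t_out = t[0] + np.arange(n_out) / 100.0
    out = np.vstack([np.interp(t_out, t, ch) for ch in x])
    return t_out, out


def segment_strides(
    foot_gyro_sagittal: np.ndarray,
    rate: float = 100.0,
    min_peak: float = DEFAULT_MIN_PEAK,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> List[Tuple[int, int]]:
    """Stride windows (start, end sample) from the sagittal foot gyro.

    Swing peaks are local maxima above ``min_peak`` separated by at least
    ``min_separation``; window k spans from the signal minimum between peaks
    k-1 and k (for the first peak: from the trace start) to the minimum
    between peaks k and k+1.
    """
    sig = np.asarray(foot_gyro_sagittal, dtype=float)
    if len(sig) < rate:
        raise ValueError("stream must be at least 1 s long")
    peaks, _ = find_peaks(sig, height=min_peak, distance=max(int(round(min_separation * rate)), 1))
    if len(peaks) < 2:
        raise SegmentationError(f"found {len(peaks)} swing peaks; need at least 2")
    bounds = []
    prev = 0
    for p in peaks:
        seg = sig[prev:p]
        bounds.append(prev + int(np.argmin(seg)))  # ties -> earlier sample
        prev = p
    windows = [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]
    return windows


def reflect_left(window: np.ndarray, side: str = "L") -> np.ndarray:
    """Mirror a left-side stride window about the sagittal plane.

    With sensor axes x anterior, y medio-lateral (left), z up, mirroring
    negates the medio-lateral acceleration ``ay`` and the angular velocities
    about the anterior and vertical axes (``gx``, ``gz``); ``ax``, ``az`` and
    the sagittal rate ``gy`` are unchanged.  Channels must be stacked in
    6-channel [ax, ay, az, gx, gy, gz] sensor blocks.
    """
    if side != "L":
        raise ValueError("reflect_left applies only to left-side strides")
    w = np.array(window, dtype=float, copy=True)
    if w.shape[0] % 6 != 0:
        raise ValueError("channel count must be a multiple of 6")
    for off in (1, 3, 5):  # ay, gx, gz
        w[off::6] *= -1.0
    return w


def normalize(
    window: np.ndarray,
    acc_range: float = DEFAULT_ACC_RANGE,
    gyro_range: float = DEFAULT_GYRO_RANGE,
) -> Tuple[np.ndarray, int]:
    """Scale channels into [-1, 1] by the full-scale sensor ranges.

    Returns the scaled window and the number of samples that exceeded the
    range and were clipped (the saturation count).
    """
    if acc_range <= 0 or gyro_range <= 0:
        raise ValueError("sensor ranges must be positive")
    w = np.array(window, dtype=float, copy=True)
    if w.shape[0] % 6 != 0:
        raise ValueError("channel count must be a multiple of 6")
    for off in range(6):
        w[off::6] /= acc_range if off < 3 else gyro_range
    n_sat = int(np.sum(np.abs(w) > 1.0))
    return np.clip(w, -1.0, 1.0), n_sat


def pad_to_fixed(window: np.ndarray, target_length: int = TARGET_LENGTH) -> Tuple[np.ndarray, int]:
    """Append trailing zeros to reach ``target_length`` samples.

    Returns the padded block and the original (valid) length.  A window
    longer than the target raises rather than silently truncating.
    """
    w = np.asarray(window, dtype=float)
    n = w.shape[-1]
    if n > target_length:
        raise OverflowError(f"window of {n} samples exceeds target length {target_length}")
    if n == target_length:
        return w.copy(), n
    pad = np.zeros(w.shape[:-1] + (target_length - n,), dtype=w.dtype)
    return np.concatenate([w, pad], axis=-1), n


@dataclass
class StrideSegment:
    """One fixed-length, normalized, labeled multichannel stride window."""

    data: np.ndarray           # (channels, 212), values in [-1, 1]
    valid_length: int
    side: str
    subject_id: str
    pace: str
    stride_start_time: float
    label: Dict[str, float]    # the 12 STGPs
    cohort: str = ""
    laterality: str = ""

    def __post_init__(self) -> None:
        d = self.data
        if d.ndim != 2 or d.shape[1] != TARGET_LENGTH:
            raise ValueError(f"data must be (channels, {TARGET_LENGTH})")
        if d.shape[0] % 6 != 0:
            raise ValueError("channel count must be a multiple of 6 per sensor")
        if not (0 < self.valid_length <= TARGET_LENGTH):
            raise ValueError("valid_length out of range")
        if np.any(np.abs(d) > 1.0 + 1e-9):
            raise ValueError("segment values exceed [-1, 1]")
        if self.valid_length < TARGET_LENGTH and np.any(d[:, self.valid_length:] != 0.0):
            raise ValueError("padding region must be exactly zero")
        missing = set(STGP_NAMES) - set(self.label)
        if missing:
            raise ValueError(f"label missing parameters: {sorted(missing)}")


def label_strides(
    window_starts: Sequence[float],
    stgp_rows: pd.DataFrame,
    tolerance: float = DEFAULT_LABEL_TOLERANCE,
) -> Tuple[List[Tuple[int, int]], int]:
    """Match IMU stride windows to marker-derived strides by start time.

    Each window is matched to the stride whose starting heel strike is
    nearest its own start and within ``tolerance``; if two windows claim the
    same stride, the closer (ties: earlier) window wins.  Returns
    ``(matches, n_dropped)`` where matches are ``(window_index, row_index)``
    pairs into the inputs.
    """
    starts = np.asarray(window_starts, dtype=float)
    row_times = stgp_rows["stride_start_time"].to_numpy()
    claimed: Dict[int, Tuple[float, int]] = {}
    for w, t in enumerate(starts):
        if len(row_times) == 0:
            continue
        j = int(np.argmin(np.abs(row_times - t)))
        dist = abs(row_times[j] - t)
        if dist > tolerance:
            continue
        if j in claimed:
            best_dist, best_w = claimed[j]
            if dist < best_dist:  # ties keep the earlier window
                claimed[j] = (dist, w)
        else:
            claimed[j] = (dist, w)
    matches = sorted((w, j) for j, (_, w) in claimed.items())
    return matches, len(starts) - len(matches)


# ---------------------------------------------------------------------------
# trial -> labeled segments


def segments_from_trial(
    trial,
    stgp: Optional[pd.DataFrame] = None,
    acc_range: float = DEFAULT_ACC_RANGE,
    gyro_range: float = DEFAULT_GYRO_RANGE,
    min_peak: float = DEFAULT_MIN_PEAK,
    tolerance: float = DEFAULT_LABEL_TOLERANCE,
) -> Tuple[List[StrideSegment], Dict[str, int]]:
    """Run the full IMU pipeline on one trial.

    ``stgp`` is the marker-derived stride table used for labels; when omitted
    it is computed from the trial's marker block.  Returns the labeled
    segments (all 7 sensors, 42 channels) and a report with counts of
    unmatched, saturated and overlong windows.
    """
    from . import mocap

    if stgp is None:
        events = mocap.GaitEvents.from_markers(trial.markers, 100.0)
        stgp = mocap.compute_stgp(trial.markers, events, 100.0)

    streams = {}
    for sensor in SENSOR_ORDER:
        _, up = resample_to_100hz(trial.imu_time, trial.imu[sensor])
        streams[sensor] = up  # (6, n)

    report = {"unmatched": 0, "saturated_samples": 0, "overlong": 0, "segments": 0}
    segments: List[StrideSegment] = []
    for side in ("L", "R"):
        gy = streams[f"foot_{side.lower()}"][4]
        windows = segment_strides(gy, 100.0, min_peak=min_peak)
        t0 = float(trial.imu_time[0])
        starts = [t0 + a / 100.0 for a, _ in windows]
        rows = stgp[stgp["side"] == side].reset_index(drop=True)
        matches, dropped = label_strides(starts, rows, tolerance)
        report["unmatched"] += dropped
        for w_idx, r_idx in matches:
            a, b = windows[w_idx]
            raw = np.vstack([streams[s][:, a:b] for s in SENSOR_ORDER])
            if side == "L":
                raw = reflect_left(raw, side)
            norm, n_sat = normalize(raw, acc_range, gyro_range)
            report["saturated_samples"] += n_sat
            try:
                data, valid = pad_to_fixed(norm)
            except OverflowError:
                report["overlong"] += 1
                continue
            row = rows.iloc[r_idx]
            segments.append(
                StrideSegment(
                    data=data.astype(np.float32),
                    valid_length=valid,
                    side=side,
                    subject_id=trial.subject_id,
                    pace=trial.pace,
                    stride_start_time=float(row["stride_start_time"]),
                    label={k: float(row[k]) for k in STGP_NAMES},
                    cohort=trial.cohort,
                    laterality=trial.laterality,
                )
            )
    report["segments"] = len(segments)
    return segments, report


@dataclass
class SegmentDataset:
    """Array container for a collection of stride segments.

    ``data`` holds all 7 sensors (42 channels); training on a sensor subset
    goes through :meth:`channel_indices`.
    """

    data: np.ndarray        # (n, 42, 212) float32
    labels: np.ndarray      # (n, 12) float64, STGP_NAMES order
    meta: pd.DataFrame      # subject_id, cohort, laterality, pace, side, ...

    @classmethod
    def from_segments(cls, segments: Sequence[StrideSegment]) -> "SegmentDataset":
        data = np.stack([s.data for s in segments]).astype(np.float32)
        labels = np.array([[s.label[k] for k in STGP_NAMES] for s in segments])
        meta = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in segments],
                "cohort": [s.cohort for s in segments],
                "laterality": [s.laterality for s in segments],
                "pace": [s.pace for s in segments],
                "side": [s.side for s in segments],
                "stride_start_time": [s.stride_start_time for s in segments],
                "valid_length": [s.valid_length for s in segments],
            }
        )
        return cls(data=data, labels=labels, meta=meta)

    def __len__(self) -> int:
        return self.data.shape[0]

    @staticmethod
    def channel_indices(sensors: Sequence[str]) -> np.ndarray:
        idx = []
        for s in sensors:
            base = SENSOR_ORDER.index(s) * 6
            idx.extend(range(base, base + 6))
        return np.asarray(idx)

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip")
            f.create_dataset("labels", data=self.labels)
            f.attrs["stgp_names"] = ",".join(STGP_NAMES)
            grp = f.create_group("meta")
            for col in self.meta.columns:
                vals = self.meta[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                grp.create_dataset(col, data=vals)

    @classmethod
    def load(cls, path: str) -> "SegmentDataset":
        with h5py.File(path, "r") as f:
            data = f["data"][...]
            labels = f["labels"][...]
            meta = {}
            for col in f["meta"]:
                vals = f["meta"][col][...]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                meta[col] = vals
        return cls(data=data, labels=labels, meta=pd.DataFrame(meta))


def build_dataset(trials) -> Tuple[SegmentDataset, Dict[str, int]]:
    """Segment and label a collection of trials into one dataset."""
    all_segments: List[StrideSegment] = []
    totals = {"unmatched": 0, "saturated_samples": 0, "overlong": 0, "segments": 0}
    for trial in trials:
        segs, rep = segments_from_trial(trial)
        all_segments.extend(segs)
        for k in totals:
            totals[k] += rep[k]
    return SegmentDataset.from_segments(all_segments), totals
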