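"""Gait events and spatiotemporal parameters from marker trajectories.

Events are found at sample resolution: heel strikes as prominent local minima
of the heel marker's vertical position, toe-offs as the instant of maximal
upward toe-marker velocity inside each stride.  The 12 STGPs are then
computed per full same-side stride:

* progression axis: unit ground-plane vector of the pelvis displacement over
  the trial (re-estimated per trial, so results are invariant to rigid
  translation and to rotation about the vertical axis);
* stride length: progression-axis heel displacement between same-side heel
  strikes; step length: progression distance from the contralateral heel (at
  its strike) to the ipsilateral heel at the closing strike; step width: the
  medio-lateral analogue; toe-out: unsigned ground-plane angle between the
  heel-to-toe axis at mid-stance and the progression axis;
* stance: heel strike to same-side toe-off; swing = stride - stance; single
  support: contralateral swing time overlapping the ipsilateral stance;
  double support = stance - single support; cadence = 2 / stride time
  (steps per second); speed = stride length / stride time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import SegmentationError
from .params import STGP_NAMES

logger = logging.getLogger(__name__)

DEFAULT_PROMINENCE_M = 0.005   # 0.5 cm
DEFAULT_MIN_SEPARATION_S = 0.4  # below the fastest plausible stride time
_MIN_TOE_VELOCITY = 1e-4        # m/s; below this an interval has no toe-off


def detect_heel_strikes(
    heel_vertical: np.ndarray,
    rate: float,
    min_separation: float = DEFAULT_MIN_SEPARATION_S,
    prominence: float = DEFAULT_PROMINENCE_M,
) -> np.ndarray:
    """Times (s) of prominent local minima of the vertical heel position."""
    z = np.asarray(heel_vertical, dtype=float)
    if z.ndim != 1:
        raise ValueError("heel_vertical must be 1-D")
    if len(z) < 2 * rate * min_separation:
        raise ValueError("trajectory too short for the requested separation")
    idx, _ = find_peaks(-z, prominence=prominence, distance=max(int(round(min_separation * rate)), 1))
    if len(idx) < 2:
        raise SegmentationError(f"found {len(idx)} heel strikes; need at least 2")
    return idx / rate


def detect_toe_offs(
    toe_vertical: np.ndarray,
    heel_strikes: np.ndarray,
    rate: float,
) -> np.ndarray:
    """Toe-off per stride: time of maximal upward toe velocity between
    consecutive same-side heel strikes."""
    hs = np.asarray(heel_strikes, dtype=float)
    if len(hs) < 2:
        raise ValueError("need at least 2 heel strikes")
    z = np.asarray(toe_vertical, dtype=float)
    vel = np.gradient(z, 1.0 / rate)
    out = []
    for a, b in zip(hs[:-1], hs[1:]):
        ia, ib = int(round(a * rate)) + 1, int(round(b * rate))
        if ib <= ia:
            raise SegmentationError("degenerate stride interval")
        seg = vel[ia:ib]
        k = int(np.argmax(seg))  # ties break toward the earlier sample
        if seg[k] <= _MIN_TOE_VELOCITY:
            raise SegmentationError(
                f"no upward toe motion between heel strikes at {a:.2f}s and {b:.2f}s"
            )
        out.append((ia + k) / rate)
    return np.asarray(out)


@dataclass
class GaitEvents:
    """Per-side ordered heel-strike and toe-off times (seconds)."""

    heel_strikes: Dict[str, np.ndarray]
    toe_offs: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for side in self.heel_strikes:
            hs = np.asarray(self.heel_strikes[side], dtype=float)
            to = np.asarray(self.toe_offs[side], dtype=float)
            if np.any(np.diff(hs) <= 0) or np.any(np.diff(to) <= 0):
                raise ValueError(f"event times for side {side} are not strictly increasing")
            for a, b in zip(hs[:-1], hs[1:]):
                n_inside = int(np.sum((to > a) & (to < b)))
                if n_inside != 1:
                    raise ValueError(
                        f"side {side}: stride [{a:.2f}, {b:.2f}] s contains "
                        f"{n_inside} toe-offs (expected 1)"
                    )
            self.heel_strikes[side] = hs
            self.toe_offs[side] = to

    @classmethod
    def from_markers(
        cls,
        markers: Dict[str, np.ndarray],
        rate: float,
        min_separation: float = DEFAULT_MIN_SEPARATION_S,
        prominence: float = DEFAULT_PROMINENCE_M,
    ) -> "GaitEvents":
        hs, to = {}, {}
        for side in ("L", "R"):
            heel = markers[f"heel_{side.lower()}"]
            toe = markers[f"toe_{side.lower()}"]
            hs[side] = detect_heel_strikes(heel[:, 2], rate, min_separation, prominence)
            to[side] = detect_toe_offs(toe[:, 2], hs[side], rate)
        return cls(heel_strikes=hs, toe_offs=to)


def _progression_axis(pelvis: np.ndarray) -> np.ndarray:
    disp = pelvis[-1, :2] - pelvis[0, :2]
    norm = np.linalg.norm(disp)
    if norm < 1e-6:
        raise ValueError("pelvis displacement too small to define a progression axis")
    return disp / norm


def compute_stgp(
    markers: Dict[str, np.ndarray],
    events: GaitEvents,
    rate: float,
) -> pd.DataFrame:
    """One row of 12 STGPs per full same-side stride.

    Strides lacking contralateral context or containing non-finite marker
    samples are dropped (logged), not imputed.
    """
    for side in ("L", "R"):
        if side not in events.heel_strikes:
            raise ValueError("both sides must be present")
    axis = _progression_axis(markers["pelvis"])
    perp = np.array([-axis[1], axis[0]])  # medio-lateral, pointing left

    rows: List[dict] = []
    for side in ("L", "R"):
        contra_side = "R" if side == "L" else "L"
        hs = events.heel_strikes[side]
        to = events.toe_offs[side]
        hs_c = events.heel_strikes[contra_side]
        to_c = events.toe_offs[contra_side]
        heel = markers[f"heel_{side.lower()}"]
        toe = markers[f"toe_{side.lower()}"]
        heel_c = markers[f"heel_{contra_side.lower()}"]

        for i in range(len(hs) - 1):
            t0, t1 = hs[i], hs[i + 1]
            tt = t1 - t0
            t_to = to[(to > t0) & (to < t1)][0]

            inside = np.where((hs_c > t0) & (hs_c < t1))[0]
            if len(inside) != 1:
                logger.info(
                    "side %s stride at %.2fs dropped: %d contralateral heel strikes",
                    side, t0, len(inside),
                )
                continue
            j = int(inside[0])

            # contralateral swing overlapping ipsilateral stance
            single = 0.0
            found = False
            for k in range(min(len(to_c), len(hs_c) - 1)):
                ov = min(hs_c[k + 1], t_to) - max(to_c[k], t0)
                if ov > 0:
                    single += ov
                    found = True
            if not found:
                logger.info(
                    "side %s stride at %.2fs dropped: no contralateral swing context",
                    side, t0,
                )
                continue

            k0, k1 = int(round(t0 * rate)), int(round(t1 * rate))
            k_to = int(round(t_to * rate))
            kc = int(round(hs_c[j] * rate))
            k_ms = (k0 + k_to) // 2  # mid-stance sample

            block = np.concatenate(
                [heel[k0:k1 + 1].ravel(), toe[k0:k1 + 1].ravel(), heel_c[kc:kc + 1].ravel()]
            )
            if not np.all(np.isfinite(block)):
                logger.info("side %s stride at %.2fs dropped: marker gap", side, t0)
                continue

            p_start = heel[k0, :2] @ axis
            p_end = heel[k1, :2] @ axis
            p_contra = heel_c[kc, :2] @ axis
            lat_end = heel[k1, :2] @ perp
            lat_contra = heel_c[kc, :2] @ perp

            foot_vec = toe[k_ms, :2] - heel[k_ms, :2]
            cross = axis[0] * foot_vec[1] - axis[1] * foot_vec[0]
            ang = np.degrees(np.arctan2(abs(cross), float(foot_vec @ axis)))
            stance = t_to - t0
            single = min(single, stance)
            sl_cm = (p_end - p_start) * 100.0
            rows.append(
                {
                    "side": side,
                    "stride_start_time": t0,
                    "step_length": (p_end - p_contra) * 100.0,
                    "stride_length": sl_cm,
                    "step_width": abs(lat_contra - lat_end) * 100.0,
                    "toe_out_angle": min(ang, 180.0 - ang),
                    "step_time": t1 - hs_c[j],
                    "stride_time": tt,
                    "stance_time": stance,
                    "swing_time": tt - stance,
                    "single_support_time": single,
                    "double_support_time": stance - single,
                    "cadence": 2.0 / tt,
                    "speed": sl_cm / tt,
                }
            )
    df = pd.DataFrame(rows, columns=["side", "stride_start_time"] + STGP_NAMES)
    return df.sort_values(["side", "stride_start_time"]).reset_index(drop=True)


def descriptive_stats(values) -> Dict[str, float]:
    """Mean, sample SD, CV (%), range and IQR of a set of scalars.

    CV is reported as NaN (undefined) when the mean is zero.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("need at least 2 finite values")
    mean = float(np.mean(v))
    sd = 0.0 if np.max(v) == np.min(v) else float(np.std(v, ddof=1))
    cv = sd / mean * 100.0 if mean != 0.0 else float("nan")
    q1, q3 = np.percentile(v, [25, 75])  # linear-interpolation quantiles
    return {
        "mean": mean,
        "sd": sd,
        "cv_percent": cv,
        "range": float(np.max(v) - np.min(v)),
        "iqr": float(q3 - q1),
    }
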