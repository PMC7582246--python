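"""Population-level gait parameter definitions and cohort defaults.

The package works with 12 spatiotemporal gait parameters (STGPs) per stride:
4 spatial (step length, stride length, step width, toe-out angle), 6 temporal
(step, stride, stance, swing, single-support and double-support time) and
2 general (cadence, speed).  Default population means and standard deviations
are tabulated per cohort (knee osteoarthritis, OA, vs. total knee
arthroplasty, TKA) and per walking pace (slow / normal / fast), in the units
conventional for gait reports: centimetres, seconds, degrees, steps/s, cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

#: Canonical STGP ordering used throughout the package (labels, CSV columns,
#: network targets, rank tables).
STGP_NAMES: List[str] = [
    "step_length",
    "stride_length",
    "step_width",
    "toe_out_angle",
    "step_time",
    "stride_time",
    "stance_time",
    "swing_time",
    "single_support_time",
    "double_support_time",
    "cadence",
    "speed",
]

SPATIAL = ["step_length", "stride_length", "step_width", "toe_out_angle"]
TEMPORAL = [
    "step_time",
    "stride_time",
    "stance_time",
    "swing_time",
    "single_support_time",
    "double_support_time",
]
GENERAL = ["cadence", "speed"]

UNITS: Dict[str, str] = {
    "step_length": "cm",
    "stride_length": "cm",
    "step_width": "cm",
    "toe_out_angle": "deg",
    "step_time": "s",
    "stride_time": "s",
    "stance_time": "s",
    "swing_time": "s",
    "single_support_time": "s",
    "double_support_time": "s",
    "cadence": "1/s",
    "speed": "cm/s",
}

COHORTS = ("OA", "TKA")
PACES = ("slow", "normal", "fast")

#: Maximum stride duration representable in a fixed 212-sample window at
#: 100 Hz.  Population configurations must keep mean + 3 SD below this.
MAX_STRIDE_TIME_S = 2.12


@dataclass(frozen=True)
class PopulationParams:
    """Mean/SD of each of the 12 STGPs for one cohort at one pace."""

    cohort: str
    pace: str
    mean: Dict[str, float]
    sd: Dict[str, float]

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.pace not in PACES:
            raise ValueError(f"unknown pace {self.pace!r}")
        missing = set(STGP_NAMES) - set(self.mean) | set(STGP_NAMES) - set(self.sd)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        for name in STGP_NAMES:
            if self.sd[name] < 0:
                raise ValueError(f"negative SD for {name}")
            # double-support means sit near zero for brisk walking; every
            # other temporal parameter must be strictly positive.
            if name in TEMPORAL and name != "double_support_time":
                if self.mean[name] <= 0:
                    raise ValueError(f"nonpositive temporal mean for {name}")
        t_mean, t_sd = self.mean["stride_time"], self.sd["stride_time"]
        if t_mean + 3.0 * t_sd > MAX_STRIDE_TIME_S:
            raise ValueError(
                "stride_time mean + 3 SD exceeds the "
                f"{MAX_STRIDE_TIME_S} s padded-window limit"
            )


# (cohort, pace) -> {parameter: (mean, sd)}.  Values are the published
# descriptive statistics of the OA/TKA gait dataset the simulator emulates.
_DEFAULTS: Dict[Tuple[str, str], Dict[str, Tuple[float, float]]] = {
    ("OA", "fast"): {
        "step_length": (66.6, 10.4),
        "stride_length": (132.9, 20.3),
        "step_width": (13.2, 5.7),
        "toe_out_angle": (23.9, 15.7),
        "step_time": (0.5, 0.1),
        "stride_time": (0.9, 0.1),
        "stance_time": (0.5, 0.1),
        "swing_time": (0.4, 0.1),
        "single_support_time": (0.4, 0.1),
        "double_support_time": (0.0, 0.1),
        "cadence": (2.2, 0.3),
        "speed": (146.7, 23.0),
    },
    ("OA", "normal"): {
        "step_length": (56.7, 9.1),
        "stride_length": (113.0, 17.4),
        "step_width": (12.9, 6.5),
        "toe_out_angle": (24.6, 17.8),
        "step_time": (0.6, 0.1),
        "stride_time": (1.1, 0.1),
        "stance_time": (0.6, 0.1),
        "swing_time": (0.5, 0.1),
        "single_support_time": (0.5, 0.1),
        "double_support_time": (0.1, 0.1),
        "cadence": (1.8, 0.2),
        "speed": (99.8, 20.2),
    },
    ("OA", "slow"): {
        "step_length": (53.2, 6.9),
        "stride_length": (106.1, 12.9),
        "step_width": (12.4, 5.1),
        "toe_out_angle": (27.4, 16.7),
        "step_time": (0.7, 0.1),
        "stride_time": (1.4, 0.2),
        "stance_time": (0.8, 0.1),
        "swing_time": (0.6, 0.1),
        "single_support_time": (0.6, 0.1),
        "double_support_time": (0.2, 0.1),
        "cadence": (1.5, 0.2),
        "speed": (80.3, 18.2),
    },
    ("TKA", "fast"): {
        "step_length": (66.0, 9.9),
        "stride_length": (132.1, 18.9),
        "step_width": (10.0, 4.3),
        "toe_out_angle": (18.9, 14.6),
        "step_time": (0.5, 0.1),
        "stride_time": (1.0, 0.1),
        "stance_time": (0.5, 0.1),
        "swing_time": (0.4, 0.0),
        "single_support_time": (0.4, 0.0),
        "double_support_time": (0.1, 0.0),
        "cadence": (2.1, 0.3),
        "speed": (139.7, 26.1),
    },
    ("TKA", "normal"): {
        "step_length": (59.1, 7.6),
        "stride_length": (118.1, 14.3),
        "step_width": (10.0, 4.9),
        "toe_out_angle": (20.8, 15.9),
        "step_time": (0.6, 0.1),
        "stride_time": (1.1, 0.1),
        "stance_time": (0.6, 0.1),
        "swing_time": (0.5, 0.0),
        "single_support_time": (0.5, 0.0),
        "double_support_time": (0.1, 0.0),
        "cadence": (1.8, 0.2),
        "speed": (105.8, 16.1),
    },
    ("TKA", "slow"): {
        "step_length": (53.7, 6.5),
        "stride_length": (107.2, 12.3),
        "step_width": (10.2, 4.0),
        "toe_out_angle": (18.4, 13.3),
        "step_time": (0.7, 0.1),
        "stride_time": (1.4, 0.2),
        "stance_time": (0.8, 0.1),
        "swing_time": (0.6, 0.1),
        "single_support_time": (0.6, 0.1),
        "double_support_time": (0.3, 0.1),
        "cadence": (1.4, 0.2),
        "speed": (77.5, 14.2),
    },
}


def default_population_params() -> Dict[Tuple[str, str], PopulationParams]:
    """Return the 6 default cohort x pace parameter sets.

    Keys are ``(cohort, pace)`` tuples, e.g. ``("OA", "fast")``.
    """
    out = {}
    for key, table in _DEFAULTS.items():
        cohort, pace = key
        out[key] = PopulationParams(
            cohort=cohort,
            pace=pace,
            mean={k: v[0] for k, v in table.items()},
            sd={k: v[1] for k, v in table.items()},
        )
    return out


@dataclass(frozen=True)
class SubjectProfile:
    """One simulated subject.

    ``offset_z`` holds per-parameter z-score offsets applied to the
    population mean: the subject's mean for parameter ``p`` at any pace is
    ``pop.mean[p] + offset_z[p] * between_sd_fraction * pop.sd[p]``.
    Drawing the offset once per subject (not per pace) makes a subject who
    walks long strides do so at every pace, which is what subject-wise
    cross-validation needs to be a meaningful test of generalisation.
    """

    subject_id: str
    cohort: str
    laterality: str  # none | unilateral | bilateral (TKA only)
    offset_z: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.cohort == "OA" and self.laterality != "none":
            raise ValueError("OA subjects have laterality 'none'")
        if self.cohort == "TKA" and self.laterality not in ("unilateral", "bilateral"):
            raise ValueError("TKA laterality must be unilateral or bilateral")


#: Fraction of the population SD attributed to between-subject differences;
#: the remainder (sqrt(1 - f^2)) is within-subject stride-to-stride noise,
#: so the pooled variance over many subjects recovers the population SD.
BETWEEN_SUBJECT_SD_FRACTION = 0.5

#: Subject offsets beyond this many (between-subject) SDs are redrawn so all
#: sampled STGPs stay positive.
_MAX_OFFSET_Z = 2.5


def make_cohort(n_oa: int, n_tka: int, seed: int) -> List[SubjectProfile]:
    """Create ``n_oa`` OA and ``n_tka`` TKA subject profiles.

    TKA laterality alternates unilateral / bilateral.  Deterministic for a
    fixed seed.
    """
    import numpy as np

    if n_oa < 0 or n_tka < 0:
        raise ValueError("subject counts must be nonnegative")
    rng = np.random.default_rng(seed)
    profiles: List[SubjectProfile] = []
    idx = 0
    for cohort, n, lat_cycle in (
        ("OA", n_oa, ["none"]),
        ("TKA", n_tka, ["unilateral", "bilateral"]),
    ):
        for j in range(n):
            z = {}
            for name in STGP_NAMES:
                val = rng.normal(0.0, 1.0)
                while abs(val) > _MAX_OFFSET_Z:
                    val = rng.normal(0.0, 1.0)
                z[name] = float(val)
            idx += 1
            profiles.append(
                SubjectProfile(
                    subject_id=f"S{idx:02d}",
                    cohort=cohort,
                    laterality=lat_cycle[j % len(lat_cycle)],
                    offset_z=z,
                )
            )
    return profiles
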