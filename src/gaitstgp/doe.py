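"""Full-factorial sensor-combination experiment.

Fifteen sensor combinations (every nonempty subset of feet, pelvis, shanks,
thighs) are evaluated under subject-wise k-fold cross-validation: each fold
holds out one OA, one unilateral-TKA and one bilateral-TKA subject as the
test set, and splits the remaining subjects' strides 80/20 into training and
validation.  Per (fold x combination x target) an ensemble member is trained
and its test-set predictions recorded; accuracy is summarized as mean error
(ME), mean absolute error (MAE), and normalized absolute percent error
(NAPE), the absolute error divided by the mean of the labeled test data for
that fold and target, x100.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .cnn import NetworkSpec, TrainingConfig, predict, train_ensemble
from .imu import SENSOR_GROUPS, SegmentDataset
from .params import STGP_NAMES

logger = logging.getLogger(__name__)

_GROUP_ORDER = "FPST"
_GROUP_SENSORS = {g: SENSOR_GROUPS[g] for g in _GROUP_ORDER}


@dataclass(frozen=True)
class SensorCombination:
    """A nonempty subset of the four sensor groups, e.g. ``FT``."""

    name: str

    def __post_init__(self) -> None:
        if not self.name or any(g not in _GROUP_ORDER for g in self.name):
            raise ValueError(f"invalid combination {self.name!r}")
        if list(self.name) != [g for g in _GROUP_ORDER if g in self.name]:
            raise ValueError(f"combination letters must be in {_GROUP_ORDER} order")

    @property
    def groups(self) -> List[str]:
        return list(self.name)

    @property
    def sensors(self) -> List[str]:
        return [s for g in self.groups for s in _GROUP_SENSORS[g]]

    @property
    def n_sensors(self) -> int:
        return len(self.sensors)

    @property
    def n_channels(self) -> int:
        return 6 * self.n_sensors

    def channel_indices(self) -> np.ndarray:
        return SegmentDataset.channel_indices(self.sensors)


def enumerate_combinations() -> List[SensorCombination]:
    """All 15 combinations, in the canonical full-factorial order
    (F, P, FP, S, FS, PS, FPS, T, FT, PT, FPT, ST, FST, PST, FPST)."""
    out = []
    for mask in range(1, 16):
        name = "".join(g for bit, g in zip((1, 2, 4, 8), _GROUP_ORDER) if mask & bit)
        out.append(SensorCombination(name))
    return out


@dataclass
class FoldSplit:
    """Subject-wise fold: 3 test subjects, 80/20 stride split elsewhere."""

    index: int
    test_subjects: List[str]
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


def make_folds(
    subjects: pd.DataFrame,
    stride_subjects: Sequence[str],
    k: int = 5,
    seed: int = 0,
) -> List[FoldSplit]:
    """Build k subject-wise folds.

    ``subjects`` needs columns ``subject_id``, ``cohort``, ``laterality``.
    Test triplets (one OA, one unilateral TKA, one bilateral TKA) are drawn
    without replacement across folds; the remaining subjects' strides are
    split 80/20 into train/validation per fold.
    """
    strata = {
        "OA": subjects.loc[subjects.cohort == "OA", "subject_id"].tolist(),
        "uni": subjects.loc[subjects.laterality == "unilateral", "subject_id"].tolist(),
        "bi": subjects.loc[subjects.laterality == "bilateral", "subject_id"].tolist(),
    }
    for name, pool in strata.items():
        if len(pool) < k:
            raise ValueError(f"need at least {k} subjects in stratum {name}, have {len(pool)}")
    rng = np.random.default_rng(seed)
    picks = {name: rng.choice(pool, size=k, replace=False) for name, pool in strata.items()}
    stride_subjects = np.asarray(stride_subjects)
    folds = []
    for i in range(k):
        test = sorted({picks["OA"][i], picks["uni"][i], picks["bi"][i]})
        is_test = np.isin(stride_subjects, test)
        rest = np.where(~is_test)[0]
        perm = rng.permutation(rest)
        n_train = int(round(0.8 * len(rest)))
        folds.append(
            FoldSplit(
                index=i + 1,
                test_subjects=list(test),
                train_idx=np.sort(perm[:n_train]),
                val_idx=np.sort(perm[n_train:]),
                test_idx=np.where(is_test)[0],
            )
        )
    return folds


def compute_metrics(
    records: pd.DataFrame,
    group_by: Sequence[str] = ("combination", "target"),
) -> pd.DataFrame:
    """Aggregate prediction records into ME/MAE/NAPE (+SD) per group.

    The NAPE denominator is the mean labeled value of the record's
    (fold, combination, target) test cell; per-record APEs are then pooled
    within each requested group.
    """
    if records.empty:
        raise ValueError("no records to aggregate")
    df = records.copy()
    df["error"] = df["predicted"] - df["label"]
    denom_keys = [k for k in ("fold", "combination", "target") if k in df.columns]
    denom = df.groupby(denom_keys)["label"].transform("mean")
    if np.any(denom == 0):
        logger.warning("zero label mean in a NAPE cell; APE undefined there")
    with np.errstate(divide="ignore", invalid="ignore"):
        df["ape"] = np.where(denom != 0, np.abs(df["error"]) / denom * 100.0, np.nan)
    rows = []
    for key, grp in df.groupby(list(group_by)):
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(group_by, key))
            | {
                "me": grp["error"].mean(),
                "me_sd": grp["error"].std(ddof=1),
                "mae": grp["error"].abs().mean(),
                "mae_sd": grp["error"].abs().std(ddof=1),
                "nape": grp["ape"].mean(),
                "nape_sd": grp["ape"].std(ddof=1),
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows)


#: scale profiles for the experiment configuration file
_PROFILES = {
    "full": {"folds": 5, "epochs": 300, "combinations": "all", "targets": "all"},
    "desk": {
        "folds": 2,
        "epochs": 60,
        "combinations": ["F"],
        "targets": ["stride_length", "stride_time"],
    },
}


def load_doe_config(path) -> dict:
    """Read a ``doe_config.yaml`` experiment description.

    Recognized keys: ``profile`` (full | desk), ``combinations`` (list of
    names or "all"), ``targets`` (list or "all"), ``folds``, ``epochs``,
    ``seed``, ``batch_size``.  Explicit keys override the profile defaults.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    profile = raw.pop("profile", "full")
    if profile not in _PROFILES:
        raise ValueError(f"unknown scale profile {profile!r}")
    cfg = dict(_PROFILES[profile])
    cfg.update(raw)
    combos = cfg["combinations"]
    cfg["combinations"] = (
        enumerate_combinations()
        if combos == "all"
        else [SensorCombination(c) for c in combos]
    )
    if cfg["targets"] == "all":
        cfg["targets"] = list(STGP_NAMES)
    cfg.setdefault("seed", 0)
    cfg.setdefault("batch_size", 32)
    return cfg


def run_doe(
    dataset: SegmentDataset,
    combinations: Sequence[SensorCombination],
    targets: Sequence[str],
    folds: Sequence[FoldSplit],
    config: TrainingConfig,
    spec_kwargs: Optional[dict] = None,
    out_dir: Optional[str] = None,
) -> pd.DataFrame:
    """Train and evaluate every (fold x combination x target) cell.

    Emits one prediction record per test stride with full grouping keys.
    With ``out_dir`` set, completed cells are cached as CSV and skipped on
    rerun; failed cells are logged and excluded, and the run continues.
    """
    for t in targets:
        if t not in STGP_NAMES:
            raise ValueError(f"unknown target {t!r}")
    out_path = Path(out_dir) if out_dir else None
    if out_path:
        out_path.mkdir(parents=True, exist_ok=True)
    all_records: List[pd.DataFrame] = []
    failures = []
    for combo, fold in itertools.product(combinations, folds):
        cell_name = f"{combo.name}_fold{fold.index}"
        cell_file = out_path / f"cell_{cell_name}.csv" if out_path else None
        if cell_file is not None and cell_file.exists():
            all_records.append(pd.read_csv(cell_file))
            continue
        ch = combo.channel_indices()
        tr_x = dataset.data[fold.train_idx][:, ch]
        va_x = dataset.data[fold.val_idx][:, ch]
        te_x = dataset.data[fold.test_idx][:, ch]
        tr_y = dataset.labels[fold.train_idx]
        va_y = dataset.labels[fold.val_idx]
        te_y = dataset.labels[fold.test_idx]
        te_meta = dataset.meta.iloc[fold.test_idx]
        # leakage guard: test subjects never appear in train/validation
        train_val_subjects = set(dataset.meta.iloc[fold.train_idx].subject_id) | set(
            dataset.meta.iloc[fold.val_idx].subject_id
        )
        assert not (set(fold.test_subjects) & train_val_subjects)
        try:
            spec = NetworkSpec(channels_in=combo.n_channels, **(spec_kwargs or {}))
            ens = train_ensemble(
                tr_x, tr_y, va_x, va_y, combo.name, targets, config, spec=spec
            )
            preds = predict(ens, te_x)
        except Exception as exc:  # noqa: BLE001 - cell failure must not kill the run
            logger.error("cell %s failed: %s", cell_name, exc)
            failures.append({"cell": cell_name, "error": str(exc)})
            continue
        recs = []
        for t in targets:
            col = STGP_NAMES.index(t)
            recs.append(
                pd.DataFrame(
                    {
                        "fold": fold.index,
                        "combination": combo.name,
                        "target": t,
                        "subject_id": te_meta["subject_id"].to_numpy(),
                        "cohort": te_meta["cohort"].to_numpy(),
                        "pace": te_meta["pace"].to_numpy(),
                        "predicted": preds[t],
                        "label": te_y[:, col],
                    }
                )
            )
        cell_df = pd.concat(recs, ignore_index=True)
        if cell_file is not None:
            cell_df.to_csv(cell_file, index=False)
        all_records.append(cell_df)
    if out_path:
        (out_path / "doe_manifest.json").write_text(
            json.dumps(
                {
                    "combinations": [c.name for c in combinations],
                    "targets": list(targets),
                    "folds": len(folds),
                    "failed_cells": failures,
                },
                indent=2,
            )
        )
    if failures:
        logger.warning("%d cells failed and were excluded", len(failures))
    if not all_records:
        raise RuntimeError("every DOE cell failed")
    return pd.concat(all_records, ignore_index=True)
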