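"""Ranking sensor combinations and distribution-shift screening.

Combinations are ranked per gait parameter by mean NAPE (rank 1 = most
accurate) and averaged within the spatial / temporal / general categories
and overall.  Statistical separation uses the Friedman test (nonparametric
repeated-measures analogue of ANOVA, with tie correction) followed by Dunn's
pairwise post hoc z-tests on the Friedman mean ranks with Bonferroni
correction over all C(15,2) = 105 pairs, and a stepwise grouping of
combinations into homogeneous subsets.  Out-of-distribution test subjects
are screened with the Jensen-Shannon divergence between a subject's stride
parameter distribution and the pooled training distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .params import GENERAL, SPATIAL, STGP_NAMES, TEMPORAL

#: exact permutation enumeration limit for the Friedman null
_EXACT_LIMIT = 200_000


# ---------------------------------------------------------------------------
# rank table


def rank_combinations(mean_nape: pd.DataFrame) -> pd.DataFrame:
    """Row-wise ascending ranks of a (parameter x combination) table, with
    category and overall average rows appended.

    Input rows must be named by STGP; ties get average ranks; missing cells
    are ranked over the available columns.  The returned frame carries the
    per-parameter ranks plus ``average_spatial``, ``average_temporal``,
    ``average_general`` and ``average`` rows (arithmetic means of the
    included parameter rows).
    """
    if mean_nape.isna().any().any():
        import warnings

        warnings.warn("missing cells; ranks computed on available columns")
    ranks = mean_nape.rank(axis=1, method="average")
    out = ranks.copy()
    groups = {
        "average_spatial": [p for p in SPATIAL if p in ranks.index],
        "average_temporal": [p for p in TEMPORAL if p in ranks.index],
        "average_general": [p for p in GENERAL if p in ranks.index],
        "average": [p for p in STGP_NAMES if p in ranks.index],
    }
    for name, rows in groups.items():
        if rows:
            out.loc[name] = ranks.loc[rows].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Friedman / Dunn / subsets


def _block_ranks(x: np.ndarray) -> np.ndarray:
    return np.vstack([stats.rankdata(row) for row in x])


def friedman_test(observations: np.ndarray) -> Tuple[float, float]:
    """Tie-corrected Friedman chi-square over a (blocks x treatments) matrix.

    For small tie-free problems the p-value is computed by exhaustive
    enumeration of within-block rank permutations; otherwise from the
    chi-square reference distribution with k-1 degrees of freedom.
    """
    x = np.asarray(observations, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 blocks and >= 2 treatments")
    n, k = x.shape
    r = _block_ranks(x)

    # Tie-corrected form (reduces to the classic statistic without ties):
    # Q = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (sum_ij r_ij^2 - n k (k+1)^2 / 4)
    def q_stat(ranks: np.ndarray) -> float:
        col_sums = ranks.sum(axis=0)
        denom = np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0
        if denom <= 0.0:
            return 0.0
        return (k - 1) * float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2)) / denom

    q = q_stat(r)
    if q == 0.0:
        return 0.0, 1.0

    has_ties = any(len(np.unique(row)) < k for row in r)
    n_perms = math.factorial(k) ** n
    if not has_ties and n_perms <= _EXACT_LIMIT:
        perms = list(itertools.permutations(range(1, k + 1)))
        count = 0
        total = 0
        for combo in itertools.product(perms, repeat=n):
            qq = q_stat(np.asarray(combo, dtype=float))
            total += 1
            if qq >= q - 1e-12:
                count += 1
        return float(q), count / total
    p = float(stats.chi2.sf(q, df=k - 1))
    return float(q), p


@dataclass
class DunnResult:
    mean_ranks: pd.Series
    p_adjusted: pd.DataFrame   # pairwise Bonferroni-adjusted p-values
    n_comparisons: int
    adjusted_alpha: float


def dunn_posthoc(
    mean_ranks: pd.Series,
    n_blocks: int,
    alpha: float = 0.05,
) -> DunnResult:
    """Dunn's pairwise z-tests on Friedman mean ranks, Bonferroni-corrected.

    The standard error of a mean-rank difference is sqrt(k(k+1)/(6n)); the
    Bonferroni factor is the number of pairs C(k,2) and the adjusted
    significance level is alpha divided by that count.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    names = list(mean_ranks.index)
    k = len(names)
    n_pairs = k * (k - 1) // 2
    se = math.sqrt(k * (k + 1) / (6.0 * n_blocks))
    padj = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        z = abs(mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(z)
        val = min(1.0, p * n_pairs)
        padj.loc[a, b] = padj.loc[b, a] = val
    return DunnResult(
        mean_ranks=mean_ranks,
        p_adjusted=padj,
        n_comparisons=n_pairs,
        adjusted_alpha=alpha / n_pairs,
    )


def homogeneous_subsets(
    mean_ranks: pd.Series,
    pairwise_p: pd.DataFrame,
    alpha: float = 0.05,
) -> List[List[str]]:
    """Stepwise homogeneous subsets of treatments ordered by mean rank.

    Treatments are sorted by mean rank; from each starting position the
    subset is extended while every within-subset pair remains non-significant
    at ``alpha``.  Maximal subsets are reported and may overlap.
    """
    order = list(mean_ranks.sort_values().index)
    subsets: List[List[str]] = []
    for start in range(len(order)):
        end = start + 1
        while end < len(order):
            cand = order[start:end + 1]
            if all(
                pairwise_p.loc[a, b] >= alpha
                for a, b in itertools.combinations(cand, 2)
            ):
                end += 1
            else:
                break
        subset = order[start:end]
        if not any(set(subset) <= set(s) for s in subsets):
            subsets.append(subset)
    return subsets


# ---------------------------------------------------------------------------
# Jensen-Shannon divergence screening


def js_divergence(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    bins: int = 30,
    base: float = math.e,
) -> float:
    """Jensen-Shannon divergence between histogram estimates of two samples.

    Histograms share equal-width bins spanning the pooled range and get a
    1e-9 additive smoothing before normalization.  The value is bounded by
    log(2) in the chosen base; identical samples give 0.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be nonempty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, bins + 1)
    p, _ = np.histogram(a, bins=edges)
    q, _ = np.histogram(b, bins=edges)
    p = p.astype(float) + 1e-9
    q = q.astype(float) + 1e-9
    p /= p.sum()
    q /= q.sum()
    m = 0.5 * (p + q)
    jsd = 0.5 * stats.entropy(p, m, base=base) + 0.5 * stats.entropy(q, m, base=base)
    return float(jsd)


def ood_screen(
    test_stgps: pd.DataFrame,
    training_pool: pd.DataFrame,
    threshold: float = 0.2,
    bins: int = 30,
    parameters: Optional[Sequence[str]] = None,
    min_strides: int = 5,
) -> pd.DataFrame:
    """Per test subject / parameter divergence from the training pool.

    Both inputs need a ``subject_id`` column plus STGP columns.  Subjects
    with fewer than ``min_strides`` strides are flagged ``insufficient_data``
    instead of scored; divergences above ``threshold`` are flagged as
    out-of-distribution.
    """
    parameters = list(parameters or STGP_NAMES)
    rows = []
    for subject, grp in test_stgps.groupby("subject_id"):
        for p in parameters:
            if len(grp) < min_strides:
                rows.append(
                    {
                        "subject_id": subject,
                        "parameter": p,
                        "jsd": np.nan,
                        "flag": "insufficient_data",
                    }
                )
                continue
            d = js_divergence(grp[p].to_numpy(), training_pool[p].to_numpy(), bins=bins)
            rows.append(
                {
                    "subject_id": subject,
                    "parameter": p,
                    "jsd": d,
                    "flag": "out_of_distribution" if d > threshold else "ok",
                }
            )
    return pd.DataFrame(rows)
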