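"""Consensus ranking of assemblies over the six contamination estimators.

Each method ranks assemblies from most (rank 1) to least contaminated,
ties averaged and missing values (e.g. the kmer method on assemblies that
are part of its own reference database) ignored; the global ranking
orders assemblies by the mean of their available per-method ranks.
Congruence between methods is measured by Spearman rank correlation over
pairwise-complete observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

METHODS = ("rRNA", "rprot", "redundancy", "kmer", "protein", "binning")

# score above which a method flags an assembly as contaminated; the
# genome-wide methods use a 1% floor because they rarely return exactly 0
DEFAULT_FLAG_THRESHOLDS = {
    "rRNA": 0.0,
    "rprot": 0.0,
    "redundancy": 0.0,
    "kmer": 1.0,
    "protein": 1.0,
    "binning": 1.0,
}

REDUNDANCY_CATEGORIES = (
    ("none", 0.0),       # == 0
    ("low", 5.0),        # <= 5
    ("moderate", 10.0),  # > 5 to <= 10
    ("high", 15.0),      # > 10 to <= 15
    ("very_high", None), # > 15
)


@dataclass(frozen=True)
class CategoryReport:
    redundancy_category: str
    ribosomal_category: int  # how many of {rRNA, rprot} flag contamination
    flagged_method_count: int


def rank_method(scores: Sequence[Optional[float]]) -> np.ndarray:
    """Descending-score ranks starting at 1, ties averaged, NaN preserved."""
    arr = np.asarray(
        [np.nan if s is None else float(s) for s in scores], dtype=float
    )
    present = ~np.isnan(arr)
    if not present.any():
        raise ValueError("all scores missing for this method")
    ranks = np.full(len(arr), np.nan)
    ranks[present] = stats.rankdata(-arr[present], method="average")
    return ranks


def consensus_rank(rank_table: pd.DataFrame) -> pd.DataFrame:
    """Average per-method ranks and derive the global ranking.

    ``rank_table`` is assemblies x methods with NaN for missing entries.
    Returns a frame with ``rank_avg`` (mean over non-missing ranks) and
    ``global_rank`` (1..N by ascending rank_avg, exact ties broken by
    assembly id).
    """
    missing_all = rank_table.isna().all(axis=1)
    if missing_all.any():
        bad = rank_table.index[missing_all].tolist()
        raise ValueError(f"assemblies with no usable method rank: {bad}")
    rank_avg = rank_table.mean(axis=1, skipna=True)
    order = sorted(rank_avg.index, key=lambda a: (rank_avg[a], str(a)))
    global_rank = pd.Series(
        {a: i + 1 for i, a in enumerate(order)}, name="global_rank"
    )
    return pd.DataFrame({"rank_avg": rank_avg, "global_rank": global_rank})


def spearman(
    x: Sequence[Optional[float]],
    y: Sequence[Optional[float]],
    pairwise_complete: bool = True,
) -> float:
    """Spearman rho: Pearson correlation of averaged-tie ranks over
    indices where both values are present."""
    xa = np.asarray([np.nan if v is None else float(v) for v in x], dtype=float)
    ya = np.asarray([np.nan if v is None else float(v) for v in y], dtype=float)
    if pairwise_complete:
        keep = ~(np.isnan(xa) | np.isnan(ya))
        xa, ya = xa[keep], ya[keep]
    if len(xa) < 3:
        raise ValueError("need at least 3 complete pairs")
    rx = stats.rankdata(xa, method="average")
    ry = stats.rankdata(ya, method="average")
    return float(stats.pearsonr(rx, ry)[0])


def correlation_matrix(scores: pd.DataFrame, with_global: bool = True) -> pd.DataFrame:
    """Spearman correlations between all methods (and the global ranking)."""
    table = scores.copy()
    if with_global:
        ranks = pd.DataFrame(
            {m: rank_method(scores[m].tolist()) for m in scores.columns},
            index=scores.index,
        )
        cons = consensus_rank(ranks)
        # negate so that "more contaminated" sorts the same way as raw scores
        table["global"] = -cons["rank_avg"]
    cols = table.columns
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            rho = spearman(table[a].tolist(), table[b].tolist())
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def categorize(
    scores: dict[str, Optional[float]],
    flag_thresholds: Optional[dict[str, float]] = None,
) -> CategoryReport:
    """Contamination categories for one assembly.

    The redundancy category follows the published banding (0 / <=5 /
    >5-10 / >10-15 / >15); the ribosomal category counts how many of the
    two ribosomal-gene methods (rRNA, rprot) return a positive score; the
    flagged count is the number of methods exceeding their per-method
    threshold.
    """
    thresholds = dict(DEFAULT_FLAG_THRESHOLDS)
    if flag_thresholds:
        thresholds.update(flag_thresholds)
    red = scores.get("redundancy")
    if red is None or (isinstance(red, float) and np.isnan(red)):
        category = "none"
    elif red == 0:
        category = "none"
    elif red <= 5:
        category = "low"
    elif red <= 10:
        category = "moderate"
    elif red <= 15:
        category = "high"
    else:
        category = "very_high"
    ribo = sum(
        1
        for m in ("rRNA", "rprot")
        if scores.get(m) is not None
        and not (isinstance(scores[m], float) and np.isnan(scores[m]))
        and scores[m] > 0
    )
    flagged = 0
    for m in METHODS:
        v = scores.get(m)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        thr = thresholds[m]
        if (v > thr) if thr == 0.0 else (v >= thr):
            flagged += 1
    return CategoryReport(category, ribo, flagged)


def build_rank_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-method averaged-tie ranks for an assemblies x methods score frame."""
    return pd.DataFrame(
        {m: rank_method(scores[m].tolist()) for m in scores.columns},
        index=scores.index,
    )


def consensus_report(scores: pd.DataFrame) -> pd.DataFrame:
    """Score matrix + per-method ranks + rank_avg + global_rank, sorted by
    the global ranking (most contaminated first)."""
    ranks = build_rank_table(scores)
    cons = consensus_rank(ranks)
    out = scores.join(ranks.add_prefix("rank_")).join(cons)
    return out.sort_values("global_rank")
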