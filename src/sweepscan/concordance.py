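"""Cross-dataset validation: align window tables from two scans, test
whether one dataset's candidate windows show shifted homozygosity in the
other, intersect significant calls, and correlate dZHp profiles."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from sweepscan.errors import ConfigurationError, DegenerateDataError, InputError

logger = logging.getLogger(__name__)

WINDOW_KEY = ["chrom", "start", "end"]

#: below this size in both groups the rank-sum null is enumerated exactly
EXACT_MAX_N = 10


@dataclass
class MatchResult:
    table: pd.DataFrame  # inner join, suffixes _a / _b
    n_matched: int
    n_a_only: int
    n_b_only: int


def match_windows(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    grid_a: Tuple[int, int] | None = None,
    grid_b: Tuple[int, int] | None = None,
) -> MatchResult:
    """Inner-join two per-window tables on (chrom, start, end).

    ``grid_a`` / ``grid_b`` are optional (size, step) pairs; a mismatch is
    an error since the join would silently be empty or misaligned.
    """
    if grid_a is not None and grid_b is not None and grid_a != grid_b:
        raise ConfigurationError(
            f"window grids differ: {grid_a} vs {grid_b}; tables are not comparable"
        )
    for name, t in (("A", table_a), ("B", table_b)):
        missing = [c for c in WINDOW_KEY if c not in t.columns]
        if missing:
            raise InputError(f"table {name} lacks key columns {missing}")
        if t.duplicated(WINDOW_KEY).any():
            raise InputError(f"table {name} has duplicate window keys")
    merged = table_a.merge(
        table_b, on=WINDOW_KEY, how="inner", suffixes=("_a", "_b")
    )
    n_matched = len(merged)
    if n_matched == 0:
        warnings.warn("no windows shared between the two tables", stacklevel=2)
    return MatchResult(
        table=merged,
        n_matched=n_matched,
        n_a_only=len(table_a) - n_matched,
        n_b_only=len(table_b) - n_matched,
    )


@dataclass
class RankShiftResult:
    p_value: float
    statistic: float  # rank-sum of the candidate windows (midranks)
    n_candidates: int
    n_background: int
    method: str  # "exact" | "normal"
    degenerate: bool = False


def _exact_rank_sum_p(candidates: np.ndarray, background: np.ndarray) -> float:
    """One-sided (greater) p by full enumeration of rank configurations.

    All C(n1+n2, n1) assignments of the pooled values to the candidate set
    are enumerated; ties are handled naturally because the statistic is
    recomputed from the pooled midranks for every assignment.
    """
    pooled = np.concatenate([candidates, background])
    ranks = sps.rankdata(pooled)  # midranks
    n1 = len(candidates)
    obs = ranks[:n1].sum()
    total = comb(len(pooled), n1)
    hits = 0
    for idx in combinations(range(len(pooled)), n1):
        if ranks[list(idx)].sum() >= obs - 1e-9:
            hits += 1
    return hits / total


def rank_shift_test(
    values: Sequence[float],
    candidate_mask: Sequence[bool],
    alternative: str = "greater",
) -> RankShiftResult:
    """Two-sample Wilcoxon rank-sum of candidate vs background windows.

    ``values`` is the statistic in the validation dataset (pass -ZHp so
    "greater" means "more homozygous"); ``candidate_mask`` flags the
    windows called in the discovery dataset. Exact null enumeration when
    both groups have <= 10 members, otherwise the normal approximation
    with tie correction. A complete tie is degenerate: p = 0.5 with a
    warning rather than a divide-by-zero.
    """
    if alternative not in ("greater", "less"):
        raise ConfigurationError(f"unknown alternative {alternative!r}")
    x = np.asarray(values, dtype=float)
    mask = np.asarray(candidate_mask, dtype=bool)
    if x.shape != mask.shape:
        raise InputError("values and candidate_mask must align")
    keep = np.isfinite(x)
    x, mask = x[keep], mask[keep]
    cand = x[mask]
    bg = x[~mask]
    if cand.size == 0:
        raise InputError("empty candidate set")
    if bg.size == 0:
        raise InputError("empty background set")
    if alternative == "less":
        cand, bg = -cand, -bg

    ranks = sps.rankdata(np.concatenate([cand, bg]))
    stat = float(ranks[: cand.size].sum())

    if np.unique(x).size == 1:
        warnings.warn(
            "all window statistics tied; rank-shift test is degenerate",
            stacklevel=2,
        )
        return RankShiftResult(0.5, stat, cand.size, bg.size, "degenerate", True)

    if cand.size <= EXACT_MAX_N and bg.size <= EXACT_MAX_N:
        p = _exact_rank_sum_p(cand, bg)
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            cand, bg, alternative="greater", method="asymptotic"
        )
        p = float(res.pvalue)
        method = "normal"
    return RankShiftResult(p, stat, cand.size, bg.size, method)


@dataclass(frozen=True)
class SharedRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    direction: str
    n_windows: int


def intersect_significant(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame
) -> Tuple[List[SharedRegion], int]:
    """Windows significant in the same direction in both datasets, merged
    into maximal regions over overlapping/adjacent grid windows.

    Inputs are window tables with columns (chrom, start, end, direction).
    Returns (merged regions, shared window count); symmetric in A and B.
    """
    key = WINDOW_KEY + ["direction"]
    for name, t in (("A", calls_a), ("B", calls_b)):
        missing = [c for c in key if c not in t.columns]
        if missing:
            raise InputError(f"calls {name} lack columns {missing}")
    shared = calls_a[key].merge(calls_b[key], on=key, how="inner")
    shared = shared.drop_duplicates().sort_values(["chrom", "start"])
    n_windows = len(shared)
    regions: List[SharedRegion] = []
    cur: Dict | None = None
    for row in shared.itertuples(index=False):
        if (
            cur is not None
            and row.chrom == cur["chrom"]
            and row.direction == cur["direction"]
            and row.start <= cur["end"] + 1
        ):
            cur["end"] = max(cur["end"], row.end)
            cur["n"] += 1
        else:
            if cur is not None:
                regions.append(
                    SharedRegion(
                        cur["chrom"], cur["start"], cur["end"], cur["direction"], cur["n"]
                    )
                )
            cur = {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "direction": row.direction,
                "n": 1,
            }
    if cur is not None:
        regions.append(
            SharedRegion(cur["chrom"], cur["start"], cur["end"], cur["direction"], cur["n"])
        )
    return regions, n_windows


def delta_correlation(
    dzhp_a: Sequence[float], dzhp_b: Sequence[float]
) -> Tuple[float, float, float]:
    """Pearson correlation of aligned dZHp profiles: (r, r^2, p)."""
    a = np.asarray(dzhp_a, dtype=float)
    b = np.asarray(dzhp_b, dtype=float)
    if a.shape != b.shape:
        raise InputError("aligned dZHp vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise InputError("need at least 3 aligned windows")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateDataError("zero variance in a dZHp vector")
    r, p = sps.pearsonr(a, b)
    return float(r), float(r) ** 2, float(p)
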