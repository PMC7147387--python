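"""Window statistics: pooled heterozygosity, Z-scores, group contrast,
Weir-Cockerham FST, and Bonferroni outlier calling.

The heterozygosity score of a window is

    Hp = 2 * A * B / (A + B)**2,   A = sum(n_MAJ), B = sum(n_MIN)

where n_MAJ / n_MIN are the read counts of the most / least abundant
allele at each SNP within one population group, and the sums run over all
SNPs in the window (sums first, then the ratio -- not a mean of per-site
values). Hp is bounded in [0, 0.5] and is standardized genome-wide within
each group to ZHp. The directional contrast is dZHp = ZHp_wild -
ZHp_farmed: positive values mark windows where the farmed group lost
heterozygosity relative to the wild group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from sweepscan.errors import ConfigurationError, DegenerateDataError, InputError
from sweepscan.windows import GenomeWindow


def window_hp(nmaj_sum, nmin_sum):
    """Pooled heterozygosity from window-summed major/minor read counts.

    Accepts scalars or arrays; returns NaN where the total count is zero
    (window undefined).
    """
    a = np.asarray(nmaj_sum, dtype=float)
    b = np.asarray(nmin_sum, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise InputError("read counts must be non-negative")
    tot = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        hp = np.where(tot > 0, 2.0 * a * b / tot**2, np.nan)
    return float(hp) if hp.ndim == 0 else hp


def z_transform(values) -> np.ndarray:
    """Standardize to mean 0, sample sd 1 (ddof=1) over the given values."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateDataError(
            "z-transform requires at least 2 distinct values"
        )
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateDataError("z-transform undefined: zero or non-finite sd")
    return (x - x.mean()) / sd


def delta_zhp(zhp_wild, zhp_farmed):
    """Directional contrast dZHp = ZHp_wild - ZHp_farmed (elementwise)."""
    w = np.asarray(zhp_wild, dtype=float)
    f = np.asarray(zhp_farmed, dtype=float)
    if w.shape != f.shape:
        raise InputError(
            f"mismatched window sets: {w.shape} vs {f.shape}"
        )
    d = w - f
    return float(d) if d.ndim == 0 else d


# ---------------------------------------------------------------------------
# Weir-Cockerham FST (allele-count form, r = 2 populations)
# ---------------------------------------------------------------------------


class FstComponents(NamedTuple):
    """Per-site variance components of the two-population theta estimator."""

    msp: float  # between-population mean square
    msg: float  # within-population mean square
    nc: float  # effective allele sample size
    num: float  # theta numerator, retained for window aggregation
    den: float  # theta denominator
    theta: float  # NaN when undefined (monomorphic)


def wc_fst_site(
    alt1: float, n1: float, alt2: float, n2: float
) -> FstComponents:
    """Weir-Cockerham theta at one site from haploid allele samples.

    ``alt_i`` is the count of one allele (consistently labelled across the
    two populations) and ``n_i`` the total allele sample size in population
    i. For pool-seq, reads are the allele samples. Monomorphic sites yield
    theta = NaN with zero components.
    """
    if n1 < 1 or n2 < 1:
        raise InputError("allele sample sizes must be >= 1 in each population")
    if not (0 <= alt1 <= n1 and 0 <= alt2 <= n2):
        raise InputError("allele counts must lie in [0, n]")
    p1 = alt1 / n1
    p2 = alt2 / n2
    ntot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / ntot
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # / (r-1) with r=2
    denom_within = (n1 - 1) + (n2 - 1)
    if denom_within > 0:
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / denom_within
    else:
        msg = 0.0
    nc = ntot - (n1 * n1 + n2 * n2) / ntot  # / (r-1) with r=2
    num = msp - msg
    den = msp + (nc - 1) * msg
    if msp == 0 and msg == 0:
        return FstComponents(0.0, 0.0, nc, 0.0, 0.0, float("nan"))
    theta = num / den if den != 0 else float("nan")
    return FstComponents(msp, msg, nc, num, den, theta)


def wc_fst_window(components: Sequence[FstComponents]) -> float:
    """Windowed theta as a ratio of sums over defined sites.

    Sum of per-site numerators over sum of denominators (the weighted
    estimator); NaN when no site contributes a non-zero denominator.
    """
    num = 0.0
    den = 0.0
    for c in components:
        if np.isnan(c.theta):
            continue
        num += c.num
        den += c.den
    return num / den if den != 0 else float("nan")


def wc_fst_sites_array(alt1, n1, alt2, n2):
    """Vectorized per-site (numerator, denominator) for window aggregation.

    Monomorphic or depth-0 sites return (0, 0) and are skipped by
    aggregation. Sample sizes < 1 in either population mark the site
    undefined rather than raising (pool depth can drop to 0).
    """
    a1 = np.asarray(alt1, dtype=float)
    a2 = np.asarray(alt2, dtype=float)
    m1 = np.asarray(n1, dtype=float)
    m2 = np.asarray(n2, dtype=float)
    ok = (m1 >= 1) & (m2 >= 1) & (m1 + m2 > 2)
    num = np.zeros_like(a1, dtype=float)
    den = np.zeros_like(a1, dtype=float)
    if not np.any(ok):
        return num, den
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(ok, a1 / np.where(m1 > 0, m1, 1), 0.0)
        p2 = np.where(ok, a2 / np.where(m2 > 0, m2, 1), 0.0)
        ntot = m1 + m2
        pbar = (m1 * p1 + m2 * p2) / np.where(ntot > 0, ntot, 1)
        msp = m1 * (p1 - pbar) ** 2 + m2 * (p2 - pbar) ** 2
        dw = np.where(ok, (m1 - 1) + (m2 - 1), 1.0)
        msg = (m1 * p1 * (1 - p1) + m2 * p2 * (1 - p2)) / dw
        nc = ntot - (m1 * m1 + m2 * m2) / np.where(ntot > 0, ntot, 1)
        defined = ok & ~((msp == 0) & (msg == 0))
        num = np.where(defined, msp - msg, 0.0)
        den = np.where(defined, msp + (nc - 1) * msg, 0.0)
    return num, den


# ---------------------------------------------------------------------------
# Outlier calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepCall:
    """A maximal run of consecutive significant windows on one chromosome."""

    chrom: str
    start: int
    end: int
    direction: Literal["farmed_loss", "wild_loss"]
    max_abs_score: float
    min_p_adj: float
    n_windows: int


def _merge_calls(
    windows: Sequence[GenomeWindow],
    sig_idx: Sequence[int],
    scores: np.ndarray,
    p_adj: np.ndarray,
    directions: Sequence[str],
) -> List[SweepCall]:
    calls: List[SweepCall] = []
    run: List[int] = []

    def flush():
        if not run:
            return
        ws = [windows[i] for i in run]
        calls.append(
            SweepCall(
                chrom=ws[0].chrom,
                start=min(w.start for w in ws),
                end=max(w.end for w in ws),
                direction=directions[run[0]],
                max_abs_score=float(np.max(np.abs(scores[run]))),
                min_p_adj=float(np.min(p_adj[run])),
                n_windows=len(run),
            )
        )
        run.clear()

    prev = None
    for i in sorted(sig_idx, key=lambda i: (windows[i].chrom, windows[i].start)):
        w = windows[i]
        if (
            prev is not None
            and w.chrom == windows[prev].chrom
            and w.start <= windows[prev].end + 1
            and directions[i] == directions[prev]
        ):
            run.append(i)
        else:
            flush()
            run.append(i)
        prev = i
    flush()
    return calls


def outlier_windows(
    windows: Sequence[GenomeWindow],
    scores,
    *,
    alpha: float | None = None,
    z_threshold: float | None = None,
    tail: Literal["upper", "lower", "both"] = "both",
    n_tests: int | None = None,
    restandardize: bool = False,
    merge: bool = True,
) -> tuple[pd.DataFrame, List[SweepCall]]:
    """Call outlier windows from per-window scores (ZHp or dZHp).

    Scores are treated as standard normal for tail p-values; with
    ``restandardize`` the score vector is re-centred/scaled first (the two
    groups' ZHp are positively correlated, so raw dZHp is under-dispersed).
    One-sided p per tail, Bonferroni-adjusted over ``n_tests`` windows
    (default: number of finite scores). Exactly one of ``alpha`` (Bonferroni
    mode) or ``z_threshold`` (fixed-threshold mode) selects significance.
    Consecutive significant windows running in the same direction merge into
    one :class:`SweepCall` unless ``merge`` is disabled.
    """
    if (alpha is None) == (z_threshold is None):
        raise ConfigurationError("specify exactly one of alpha or z_threshold")
    if alpha is not None and not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")

    s = np.asarray(scores, dtype=float)
    if len(windows) != s.size:
        raise InputError("scores length must match window list")
    finite = np.isfinite(s)
    if n_tests is None:
        n_tests = int(finite.sum())
    if restandardize:
        z = np.full_like(s, np.nan)
        z[finite] = z_transform(s[finite])
    else:
        z = s

    p_upper = sps.norm.sf(z)
    p_lower = sps.norm.cdf(z)
    padj_upper = np.minimum(1.0, n_tests * p_upper)
    padj_lower = np.minimum(1.0, n_tests * p_lower)

    if z_threshold is not None:
        sig_up = finite & (z > z_threshold)
        sig_lo = finite & (z < -z_threshold)
    else:
        sig_up = finite & (padj_upper < alpha)
        sig_lo = finite & (padj_lower < alpha)
    if tail == "upper":
        sig_lo[:] = False
    elif tail == "lower":
        sig_up[:] = False

    direction = np.where(z > 0, "farmed_loss", "wild_loss")
    table = pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "score": s,
            "z_used": z,
            "p_upper": p_upper,
            "p_lower": p_lower,
            "p_adj_upper": padj_upper,
            "p_adj_lower": padj_lower,
            "significant": sig_up | sig_lo,
            "direction": direction,
        }
    )

    sig_idx = np.nonzero(sig_up | sig_lo)[0]
    p_adj_best = np.where(z > 0, padj_upper, padj_lower)
    if merge:
        calls = _merge_calls(windows, sig_idx, z, p_adj_best, direction)
    else:
        calls = [
            SweepCall(
                chrom=windows[i].chrom,
                start=windows[i].start,
                end=windows[i].end,
                direction=str(direction[i]),
                max_abs_score=float(abs(z[i])),
                min_p_adj=float(p_adj_best[i]),
                n_windows=1,
            )
            for i in sig_idx
        ]
    return table, calls


# ---------------------------------------------------------------------------
# Full per-window scan table
# ---------------------------------------------------------------------------


def compute_window_stats(
    windows: Sequence[GenomeWindow],
    window_sites: Sequence[np.ndarray],
    group_ref: Mapping[str, np.ndarray],
    group_alt: Mapping[str, np.ndarray],
    *,
    wild: str,
    farmed: str,
    min_snps: int = 20,
    restandardize: bool = False,
) -> pd.DataFrame:
    """Assemble the per-window statistics table for a two-group scan.

    ``group_ref`` / ``group_alt`` give each group's summed ref / alt read
    counts per site (aligned with the site indices in ``window_sites``).
    Per group and window: informative-SNP count, sum(n_MAJ), sum(n_MIN),
    Hp, and genome-wide ZHp over that group's retained windows. Contrast
    columns (dZHp, FST, tail p-values) are filled only where both groups
    retain the window.
    """
    groups = list(group_ref)
    if wild not in groups or farmed not in groups:
        raise ConfigurationError(
            f"wild={wild!r} and farmed={farmed!r} must both be groups "
            f"({groups})"
        )
    n_win = len(windows)
    df = pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
        }
    )

    per_group_hp: Dict[str, np.ndarray] = {}
    retained: Dict[str, np.ndarray] = {}
    for g in groups:
        ref = np.asarray(group_ref[g], dtype=np.int64)
        alt = np.asarray(group_alt[g], dtype=np.int64)
        nmaj = np.maximum(ref, alt)
        nmin = np.minimum(ref, alt)
        informative = (ref + alt) > 0
        nsnp = np.zeros(n_win, dtype=np.int64)
        a_sum = np.zeros(n_win, dtype=np.int64)
        b_sum = np.zeros(n_win, dtype=np.int64)
        for i, idx in enumerate(window_sites):
            if idx.size == 0:
                continue
            inf = idx[informative[idx]]
            nsnp[i] = inf.size
            a_sum[i] = nmaj[inf].sum()
            b_sum[i] = nmin[inf].sum()
        keep = nsnp >= min_snps
        hp = np.full(n_win, np.nan)
        hp[keep] = window_hp(a_sum[keep], b_sum[keep])
        zhp = np.full(n_win, np.nan)
        if keep.sum() >= 2:
            zhp[keep] = z_transform(hp[keep])
        per_group_hp[g] = hp
        retained[g] = keep
        df[f"nsnp_{g}"] = nsnp
        df[f"nmaj_{g}"] = a_sum
        df[f"nmin_{g}"] = b_sum
        df[f"hp_{g}"] = hp
        df[f"zhp_{g}"] = zhp
        df[f"retained_{g}"] = keep

    both = retained[wild] & retained[farmed]
    dz = np.full(n_win, np.nan)
    dz[both] = df.loc[both, f"zhp_{wild}"] - df.loc[both, f"zhp_{farmed}"]
    df["dzhp"] = dz

    # windowed Weir-Cockerham FST between the two contrast groups
    num_site, den_site = wc_fst_sites_array(
        np.asarray(group_alt[farmed], dtype=float),
        np.asarray(group_ref[farmed], dtype=float)
        + np.asarray(group_alt[farmed], dtype=float),
        np.asarray(group_alt[wild], dtype=float),
        np.asarray(group_ref[wild], dtype=float)
        + np.asarray(group_alt[wild], dtype=float),
    )
    fst = np.full(n_win, np.nan)
    for i, idx in enumerate(window_sites):
        if not both[i] or idx.size == 0:
            continue
        d = den_site[idx].sum()
        fst[i] = num_site[idx].sum() / d if d != 0 else np.nan
    df["fst"] = fst

    score = dz.copy()
    if restandardize and np.isfinite(dz).sum() >= 2:
        fin = np.isfinite(dz)
        score[fin] = z_transform(dz[fin])
    df["dzhp_z"] = score
    fin = np.isfinite(score)
    n_tests = int(fin.sum())
    df.attrs["n_tests"] = n_tests
    p_up = np.full(n_win, np.nan)
    p_lo = np.full(n_win, np.nan)
    p_up[fin] = sps.norm.sf(score[fin])
    p_lo[fin] = sps.norm.cdf(score[fin])
    df["p_upper"] = p_up
    df["p_lower"] = p_lo
    df["p_adj_upper"] = np.minimum(1.0, n_tests * p_up)
    df["p_adj_lower"] = np.minimum(1.0, n_tests * p_lo)
    return df
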