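"""Fixed sliding-window grid construction and SNP-to-window assignment.

Windows are 1-based inclusive internally (start, end); BED export converts
to 0-based half-open. Only full-length windows are emitted: a chromosome
shorter than one window size contributes no windows, and trailing partial
windows are dropped so every window has identical span.
"""

from __future__ import annotations

import os
from typing import Dict, List, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from sweepscan.errors import ConfigurationError, InputError

DEFAULT_WINDOW_SIZE = 150_000
DEFAULT_WINDOW_STEP = 75_000
DEFAULT_MIN_SNPS = 20


class GenomeWindow(NamedTuple):
    """One grid cell, coordinates 1-based inclusive."""

    chrom: str
    start: int
    end: int
    index: int


def read_chrom_lengths(path: str) -> Dict[str, int]:
    """Read chromosome lengths from a samtools ``.fai`` index or a 2-column TSV.

    Both formats put the sequence name in column 1 and its length in
    column 2; extra ``.fai`` columns are ignored.
    """
    lengths: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(
                    f"{os.path.basename(path)}:{lineno}: expected at least 2 "
                    f"tab-separated columns (name, length)"
                )
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise InputError(
                    f"{os.path.basename(path)}:{lineno}: length {parts[1]!r} "
                    f"is not an integer"
                ) from exc
            if name in lengths:
                raise InputError(f"duplicate chromosome {name!r} in {path}")
            lengths[name] = length
    if not lengths:
        raise InputError(f"no chromosome lengths found in {path}")
    return lengths


def make_windows(
    chrom_lengths: Mapping[str, int],
    size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_WINDOW_STEP,
) -> List[GenomeWindow]:
    """Build the overlapping window grid over every chromosome.

    Starts are 1, 1+step, 1+2*step, ...; a window is emitted only if it
    fits entirely on the chromosome (end <= length). Windows are ordered
    by chromosome (input order) then start, and indexed globally.
    """
    if size <= 0 or step <= 0:
        raise ConfigurationError("window size and step must be positive")
    if step > size:
        raise ConfigurationError(
            f"window step ({step}) must not exceed window size ({size})"
        )
    windows: List[GenomeWindow] = []
    idx = 0
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ConfigurationError(f"chromosome {chrom!r} has length {length}")
        n = (length - size) // step + 1 if length >= size else 0
        for k in range(n):
            start = 1 + k * step
            windows.append(GenomeWindow(chrom, start, start + size - 1, idx))
            idx += 1
    return windows


def windows_to_frame(windows: Sequence[GenomeWindow]) -> pd.DataFrame:
    return pd.DataFrame(windows, columns=["chrom", "start", "end", "index"])


def assign_sites(
    windows: Sequence[GenomeWindow],
    chroms: Sequence[str],
    positions: Sequence[int],
    *,
    size: int | None = None,
    step: int | None = None,
    known_chroms: Sequence[str] | None = None,
) -> List[np.ndarray]:
    """Map each window to the indices of the sites it contains.

    A site at position p belongs to window [s, e] iff s <= p <= e; with a
    half-size step an interior site falls in exactly two windows. Sites on
    chromosomes absent from the grid's length table raise. Returns one
    index array per window, in window order.
    """
    if size is None or step is None:
        if not windows:
            return []
        size = windows[0].end - windows[0].start + 1
        starts_by_chrom: Dict[str, List[int]] = {}
        for w in windows:
            starts_by_chrom.setdefault(w.chrom, []).append(w.start)
        step = None
        for ss in starts_by_chrom.values():
            if len(ss) >= 2:
                step = ss[1] - ss[0]
                break
        if step is None:
            step = size

    by_chrom: Dict[str, List[GenomeWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)

    grid_chroms = set(by_chrom)
    # chromosomes shorter than one window carry no windows but are still
    # legitimate site locations when listed in the length table
    allowed = grid_chroms if known_chroms is None else grid_chroms | set(known_chroms)
    out: List[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in windows]
    buckets: Dict[int, List[int]] = {}

    chrom_arr = np.asarray(chroms)
    pos_arr = np.asarray(positions, dtype=np.int64)
    for chrom in pd.unique(chrom_arr):
        sel = np.nonzero(chrom_arr == chrom)[0]
        if chrom not in allowed:
            raise InputError(
                f"site(s) on chromosome {chrom!r} absent from the length table"
            )
        if chrom not in grid_chroms:
            continue
        wins = by_chrom[chrom]
        n_win = len(wins)
        p = pos_arr[sel]
        # window k (0-based within chrom) spans [1+k*step, size+k*step]
        k_lo = np.ceil((p - size) / step).astype(np.int64)
        k_hi = (p - 1) // step
        np.clip(k_lo, 0, n_win - 1, out=k_lo)
        np.clip(k_hi, -1, n_win - 1, out=k_hi)
        for site_idx, lo, hi in zip(sel, k_lo, k_hi):
            for k in range(lo, hi + 1):
                w = wins[k]
                if w.start <= pos_arr[site_idx] <= w.end:
                    buckets.setdefault(w.index, []).append(site_idx)
    for widx, idxs in buckets.items():
        out[widx] = np.asarray(sorted(idxs), dtype=np.int64)
    return out


def retain_windows(
    snp_counts: Mapping[str, np.ndarray], min_snps: int = DEFAULT_MIN_SNPS
) -> Dict[str, np.ndarray]:
    """Per-group retention mask: a window is kept for a group iff it holds
    at least ``min_snps`` informative SNPs in that group."""
    if min_snps < 0:
        raise ConfigurationError("min_snps must be non-negative")
    return {
        group: np.asarray(counts) >= min_snps for group, counts in snp_counts.items()
    }
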