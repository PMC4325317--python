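"""Calling of unmethylated (U) and methylated (M) regions from per-CpG
profiles, U->M / M->U DMR calling between paired cell types, and
pattern-by-category summaries.

The region caller is a deliberately simple, fully specified run scanner: a
region is a maximal run of at least `min_cpg` consecutive CpGs that all
qualify for the same state (level <= u_max for U, level >= m_min for M) with
no inter-CpG gap exceeding `max_gap`.  Partially methylated CpGs break runs
and are never assigned to a region.  This is a transparent stand-in for
published hotspot-extension segmentation tools; all thresholds are explicit
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DMR_CLASSES = ("UM", "MU")  # U->M and M->U in the cell1 -> cell2 direction


@dataclass(frozen=True)
class PatternParams:
    u_max: float = 0.25
    m_min: float = 0.75
    min_cpg: int = 4
    max_gap: int = 500
    min_coverage: int = 4

    def __post_init__(self):
        if not 0 <= self.u_max < self.m_min <= 1:
            raise ValueError("require 0 <= u_max < m_min <= 1")
        if self.min_cpg < 1 or self.max_gap < 0 or self.min_coverage < 0:
            raise ValueError("min_cpg >= 1, max_gap >= 0, min_coverage >= 0")


def call_patterns(profile: pd.DataFrame, params: PatternParams | None = None) -> pd.DataFrame:
    """Call U/M regions from a per-CpG profile.

    `profile` columns: chrom, pos, count_methylated, count_total (positions
    strictly increasing within each chromosome).  Returns a BED-like frame
    with columns chrom, start, end, pattern, n_cpg, mean_level; the interval
    spans the first to the last CpG of the run (end = last position + 1).
    """
    params = params or PatternParams()
    if len(profile) == 0:
        return _empty_regions()
    rows = []
    for chrom, grp in profile.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")
        total = grp["count_total"].to_numpy(dtype=np.int64)
        meth = grp["count_methylated"].to_numpy(dtype=np.int64)
        if np.any(meth > total) or np.any(meth < 0):
            raise ValueError("methylated counts must lie in [0, total]")
        keep = total >= max(params.min_coverage, 1)  # zero-coverage CpGs have no level
        pos, total, meth = pos[keep], total[keep], meth[keep]
        if pos.size == 0:
            continue
        level = meth / total
        state = np.where(level <= params.u_max, 0, np.where(level >= params.m_min, 1, -1))

        new_run = np.ones(pos.size, dtype=bool)
        if pos.size > 1:
            new_run[1:] = (np.diff(pos) > params.max_gap) | (state[1:] != state[:-1])
        starts_idx = np.flatnonzero(new_run)
        counts = np.diff(starts_idx, append=pos.size)
        run_state = state[starts_idx]
        level_sums = np.add.reduceat(level, starts_idx)

        ok = (run_state >= 0) & (counts >= params.min_cpg)
        for ri in np.flatnonzero(ok):
            i0 = starts_idx[ri]
            i1 = i0 + counts[ri] - 1
            rows.append(
                (
                    chrom,
                    int(pos[i0]),
                    int(pos[i1]) + 1,
                    "U" if run_state[ri] == 0 else "M",
                    int(counts[ri]),
                    float(level_sums[ri] / counts[ri]),
                )
            )
    if not rows:
        return _empty_regions()
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "pattern", "n_cpg", "mean_level"])


def _empty_regions() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "start", "end", "pattern", "n_cpg", "mean_level"])


def call_dmrs(
    patterns_1: pd.DataFrame, patterns_2: pd.DataFrame, min_frac: float = 0.0
) -> pd.DataFrame:
    """Emit U->M / M->U DMRs from two cell types' region calls.

    For every overlapping pair with opposite patterns the intersection is
    emitted, typed by the cell1 -> cell2 direction ("UM" or "MU").
    Same-pattern overlaps emit nothing.  An opposite-pattern overlap is
    already a confident per-CpG disagreement in both cells, so every
    intersection is emitted by default; `min_frac` optionally additionally
    requires the overlap to cover that fraction of the shorter region,
    which is conservative but rejects genuine single-segment flips whose
    flanks merge asymmetrically into neighbouring regions in the two cells.
    """
    rows = []
    for chrom in sorted(set(patterns_1["chrom"]).intersection(set(patterns_2["chrom"]))):
        a = patterns_1[patterns_1["chrom"] == chrom].sort_values("start").to_numpy()
        b = patterns_2[patterns_2["chrom"] == chrom].sort_values("start").to_numpy()
        ia = a[:, [1, 2]].astype(np.int64)
        ib = b[:, [1, 2]].astype(np.int64)
        pa = patterns_1[patterns_1["chrom"] == chrom].sort_values("start")["pattern"].to_numpy()
        pb = patterns_2[patterns_2["chrom"] == chrom].sort_values("start")["pattern"].to_numpy()
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i, 0], ib[j, 0])
            e = min(ia[i, 1], ib[j, 1])
            if e > s and pa[i] != pb[j]:
                shorter = min(ia[i, 1] - ia[i, 0], ib[j, 1] - ib[j, 0])
                if e - s >= min_frac * shorter:
                    cls = "UM" if pa[i] == "U" else "MU"
                    rows.append((chrom, int(s), int(e), cls))
            if ia[i, 1] <= ib[j, 1]:
                i += 1
            else:
                j += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "dmr_class"])


def pattern_distribution(regions: pd.DataFrame, category_col: str = "category"):
    """Counts and within-pattern proportions per (pattern x category), plus a
    chi-square test of pattern-by-category association (no continuity
    correction, matching the textbook statistic)."""
    if len(regions) == 0:
        raise ValueError("no regions to summarize")
    counts = pd.crosstab(regions["pattern"], regions[category_col])
    proportions = counts.div(counts.sum(axis=1), axis=0)
    table = counts.to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return counts, proportions, float(chi2), float(p)
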