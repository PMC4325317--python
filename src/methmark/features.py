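"""Sequence features (GC content, CpG O/E), per-mark RPKM signals,
fold changes, feature-methylation correlations and mark-signature
clustering.

Definitions
-----------
* GC content of a window of length L: (N_C + N_G) / L.
* CpG observed/expected ratio: (N_CpG * L) / (N_C * N_G), computed on the
  plus strand; defined as 0 when N_C * N_G = 0.
* RPKM of a mark in a region: (Reads + p) * 1e9 / (N * Length), where N is
  the mark's total mapped reads and p a pseudocount that keeps the signal
  strictly positive.  The default p = N / 1e9 puts the zero-read floor at
  exactly 1 / Length, independent of library size.
* A read is counted in a region iff its start coordinate lies in the region
  (avoids double counting across adjacent regions).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .synthetic import MarkReads

SEQ_FEATURES = ("gc_content", "cpg_oe")


def gc_content(seq: str) -> float:
    if len(seq) < 1:
        raise ValueError("window must have length >= 1")
    s = seq.upper()
    return (s.count("C") + s.count("G")) / len(s)


def cpg_oe(seq: str) -> float:
    if len(seq) < 2:
        raise ValueError("window must have length >= 2")
    s = seq.upper()
    n_c, n_g = s.count("C"), s.count("G")
    if n_c * n_g == 0:
        return 0.0
    return s.count("CG") * len(s) / (n_c * n_g)


def rpkm_signal(reads: int, length: int, n_total: int, pseudocount_mode: str = "n_over_1e9") -> float:
    """Pseudocounted RPKM; `pseudocount_mode` is 'n_over_1e9' or 'fixed:<c>'."""
    if n_total < 1:
        raise ValueError("total mapped reads N must be >= 1")
    if length < 1:
        raise ValueError("region length must be >= 1")
    if pseudocount_mode == "n_over_1e9":
        p = n_total / 1e9
    elif pseudocount_mode.startswith("fixed:"):
        p = float(pseudocount_mode.split(":", 1)[1])
    else:
        raise ValueError(f"unknown pseudocount_mode {pseudocount_mode!r}")
    return (reads + p) * 1e9 / (n_total * length)


def log2_fold_change(signal_1: float, signal_2: float):
    """log2(signal_2 / signal_1); inputs must be positive (the RPKM
    pseudocount guarantees this)."""
    return np.log2(np.asarray(signal_2) / np.asarray(signal_1))


def feature_matrix(
    regions: pd.DataFrame,
    sequences: dict[str, str],
    marks: dict[str, MarkReads],
    pseudocount_mode: str = "n_over_1e9",
) -> pd.DataFrame:
    """One row per region: identifying columns carried over from `regions`
    plus gc_content, cpg_oe and one RPKM column per mark (in dict order)."""
    missing = sorted(set(regions["chrom"]) - set(sequences))
    if missing:
        raise KeyError(f"regions on chromosomes absent from genome: {missing}")
    out = regions.reset_index(drop=True).copy()
    n = len(out)
    gc = np.empty(n)
    oe = np.empty(n)
    chroms = out["chrom"].to_numpy()
    starts = out["start"].to_numpy(dtype=np.int64)
    ends = out["end"].to_numpy(dtype=np.int64)
    for i in range(n):
        seq = sequences[chroms[i]][starts[i] : ends[i]]
        gc[i] = gc_content(seq)
        oe[i] = cpg_oe(seq) if len(seq) >= 2 else 0.0
    out["gc_content"] = gc
    out["cpg_oe"] = oe
    lengths = ends - starts
    for name, track in marks.items():
        vals = np.empty(n)
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            s = track.starts.get(chrom, np.empty(0, dtype=np.int64))
            counts = np.searchsorted(s, ends[sel], "left") - np.searchsorted(s, starts[sel], "left")
            vals[sel] = [
                rpkm_signal(int(c), int(ln), track.n_total, pseudocount_mode)
                for c, ln in zip(counts, lengths[sel])
            ]
        out[name] = vals
    return out


def correlate_features(matrix: pd.DataFrame, levels, feature_names: list[str]) -> pd.DataFrame:
    """Pearson r between each feature column and the per-region mean
    methylation level.  Features with zero variance (or a degenerate level
    vector) are reported with r = NaN and flagged, never as 0."""
    y = np.asarray(levels, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 regions")
    rows = []
    y_degenerate = np.std(y) == 0
    for f in feature_names:
        x = matrix[f].to_numpy(dtype=float)
        if y_degenerate or np.std(x) == 0:
            rows.append((f, np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((f, float(r), float(p), True))
    return pd.DataFrame(rows, columns=["feature", "pearson_r", "p_value", "defined"])


def mean_signal_matrix(feature_df: pd.DataFrame, mark_names: list[str], group_cols: list[str]) -> pd.DataFrame:
    """Mean log2(RPKM) signature per group (e.g. pattern x category x cell),
    rows indexed by the group key, columns the marks."""
    logged = feature_df[group_cols + list(mark_names)].copy()
    logged[list(mark_names)] = np.log2(logged[list(mark_names)].to_numpy(dtype=float))
    return logged.groupby(group_cols, sort=True).mean()


def cluster_signatures(signal_matrix: pd.DataFrame):
    """Average-linkage hierarchical clustering of row signatures under
    Euclidean distance.  Returns (linkage matrix, leaf labels in dendrogram
    order); deterministic given the matrix."""
    if len(signal_matrix) < 2:
        raise ValueError("need at least 2 rows to cluster")
    link = hierarchy.linkage(signal_matrix.to_numpy(dtype=float), method="average", metric="euclidean")
    order = hierarchy.leaves_list(link)
    labels = [signal_matrix.index[i] for i in order]
    return link, labels
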