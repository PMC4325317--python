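"""Readers and writers for the plain-text genomics formats used throughout.

All BED output is 0-based half-open.  Per-CpG methylation tables follow the
Bismark coverage convention (1-based inclusive positions, percent methylation,
methylated and unmethylated read counts); positions are converted to 0-based
on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

BED3_COLS = ["chrom", "start", "end"]
BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]
COVERAGE_COLS = ["chrom", "pos", "level_pct", "count_methylated", "count_unmethylated"]


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a plain dict of upper-case sequences."""
    fa = Fasta(str(path), rebuild=True, build_index=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED6_COLS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = (BED6_COLS + list(df.columns[6:]))[: df.shape[1]]
    return df


def write_coverage(profile: pd.DataFrame, path: str | Path) -> None:
    """Write a per-CpG profile (chrom, pos, count_methylated, count_total)
    as a Bismark-coverage-style table."""
    total = profile["count_total"].to_numpy()
    meth = profile["count_methylated"].to_numpy()
    out = pd.DataFrame(
        {
            "chrom": profile["chrom"],
            "start": profile["pos"] + 1,
            "end": profile["pos"] + 1,
            "level_pct": np.round(100.0 * meth / total, 6),
            "count_methylated": meth,
            "count_unmethylated": total - meth,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_coverage(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "level_pct", "count_methylated", "count_unmethylated"],
    )
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"] - 1,
            "count_methylated": df["count_methylated"],
            "count_total": df["count_methylated"] + df["count_unmethylated"],
        }
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
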