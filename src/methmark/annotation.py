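"""Partition a genome into promoter / gene body / downstream / intergenic
categories and assign called regions to them by midpoint.

Window definitions (0-based half-open, in transcription orientation):

* promoter    = [TSS - 1000, TSS + 500)
* gene body   = bases strictly beyond TSS + 500 and strictly before TTS - 500,
  i.e. [TSS + 501, TTS - 500)
* downstream  = [TTS - 500, TTS + 1000)
* intergenic  = everything else

Promoter and downstream windows are 1,500 bp wide (clipping at chromosome
edges aside).  The single base at exactly TSS + 500 is excluded from both the
promoter and the gene body by the strict inequalities and therefore falls to
intergenic; it never hosts a region midpoint in practice.  Overlapping
windows from different genes are resolved with the precedence
promoter > gene_body > downstream.  CpG-island membership is an independent
overlay, also decided at the region midpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("promoter", "gene_body", "downstream", "intergenic")
PRECEDENCE = ("promoter", "gene_body", "downstream")

PROMOTER_UP = 1000
PROMOTER_DOWN = 500
DOWNSTREAM_UP = 500
DOWNSTREAM_DOWN = 1000


@dataclass(frozen=True)
class GeneModel:
    """A transcript span with strand; TSS/TTS are derived from the strand
    (for '-' genes the TSS sits at the end coordinate side)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval for gene {self.id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")

    def windows(self) -> dict[str, tuple[int, int]]:
        s, e = self.start, self.end
        if self.strand == "+":
            return {
                "promoter": (s - PROMOTER_UP, s + PROMOTER_DOWN),
                "gene_body": (s + PROMOTER_DOWN + 1, e - DOWNSTREAM_UP),
                "downstream": (e - DOWNSTREAM_UP, e + DOWNSTREAM_DOWN),
            }
        return {
            "promoter": (e - PROMOTER_DOWN, e + PROMOTER_UP),
            "gene_body": (s + DOWNSTREAM_UP, e - PROMOTER_DOWN - 1),
            "downstream": (s - DOWNSTREAM_DOWN, s + DOWNSTREAM_UP),
        }


def genes_from_bed(genes: pd.DataFrame) -> list[GeneModel]:
    return [
        GeneModel(str(r.name_), str(r.chrom), int(r.start), int(r.end), str(r.strand))
        for r in genes.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def _merge(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals -> sorted disjoint (starts, ends)."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    starts, ends = [], []
    for s, e in ivs:
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


class RegionMap:
    """Category lookup over one genome: promoter/gene_body/downstream unions
    per chromosome, with intergenic as the complement."""

    def __init__(self, index: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]], chrom_sizes: dict[str, int]):
        self._index = index
        self.chrom_sizes = dict(chrom_sizes)

    def classify_point(self, chrom: str, pos: int) -> str:
        if chrom not in self._index:
            raise KeyError(f"chromosome {chrom!r} not in region map")
        per_cat = self._index[chrom]
        for cat in PRECEDENCE:
            starts, ends = per_cat[cat]
            i = np.searchsorted(starts, pos, "right") - 1
            if i >= 0 and pos < ends[i]:
                return cat
        return "intergenic"

    def classify_region(self, chrom: str, start: int, end: int) -> str:
        return self.classify_point(chrom, (start + end) // 2)

    def to_frame(self) -> pd.DataFrame:
        """Explicit disjoint tiling of every chromosome by the four
        categories, after precedence resolution."""
        rows = []
        for chrom, size in self.chrom_sizes.items():
            per_cat = self._index[chrom]
            cuts = {0, size}
            for cat in PRECEDENCE:
                starts, ends = per_cat[cat]
                cuts.update(int(x) for x in np.clip(starts, 0, size))
                cuts.update(int(x) for x in np.clip(ends, 0, size))
            edges = sorted(cuts)
            prev_cat, run_start = None, 0
            for a, b in zip(edges[:-1], edges[1:]):
                if b <= a:
                    continue
                cat = self.classify_point(chrom, a)
                if cat != prev_cat:
                    if prev_cat is not None:
                        rows.append((chrom, run_start, a, prev_cat))
                    prev_cat, run_start = cat, a
            if prev_cat is not None:
                rows.append((chrom, run_start, size, prev_cat))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def build_region_map(genes: list[GeneModel], chrom_sizes: dict[str, int]) -> RegionMap:
    """Union each gene's windows per category (multiple transcripts merge),
    clip to chromosome bounds, and return the lookup index."""
    raw: dict[str, dict[str, list[tuple[int, int]]]] = {
        c: {cat: [] for cat in PRECEDENCE} for c in chrom_sizes
    }
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise KeyError(f"gene {g.id} on unknown chromosome {g.chrom}")
        size = chrom_sizes[g.chrom]
        w = g.windows()
        if w["gene_body"][1] <= w["gene_body"][0]:
            logger.warning("gene %s shorter than ~1 kb: empty gene body", g.id)
        for cat, (s, e) in w.items():
            s, e = max(0, s), min(size, e)
            if e > s:
                raw[g.chrom][cat].append((s, e))
    index = {
        chrom: {cat: _merge(ivs) for cat, ivs in per_cat.items()}
        for chrom, per_cat in raw.items()
    }
    return RegionMap(index, chrom_sizes)


def classify_regions(regions: pd.DataFrame, region_map: RegionMap) -> pd.Series:
    """Vector of category labels, one per region row (midpoint rule)."""
    cats = [
        region_map.classify_region(r.chrom, int(r.start), int(r.end))
        for r in regions.itertuples(index=False)
    ]
    return pd.Series(cats, index=regions.index, name="category")


def overlay_cpg_islands(regions: pd.DataFrame, islands: pd.DataFrame) -> pd.Series:
    """True where the region midpoint lies inside a CpG island
    (half-open: a midpoint at an island's end coordinate is outside)."""
    flags = np.zeros(len(regions), dtype=bool)
    if len(islands) == 0 or len(regions) == 0:
        return pd.Series(flags, index=regions.index, name="cpg_island")
    for chrom, isl in islands.groupby("chrom"):
        isl = isl.sort_values("start")
        s = isl["start"].to_numpy()
        e = isl["end"].to_numpy()
        sel = regions["chrom"] == chrom
        if not sel.any():
            continue
        mids = ((regions.loc[sel, "start"] + regions.loc[sel, "end"]) // 2).to_numpy()
        idx = np.searchsorted(s, mids, "right") - 1
        ok = idx >= 0
        hit = np.zeros(mids.shape, dtype=bool)
        hit[ok] = mids[ok] < e[idx[ok]]
        flags[np.flatnonzero(sel.to_numpy())] = hit
    return pd.Series(flags, index=regions.index, name="cpg_island")
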