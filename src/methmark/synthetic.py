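"""Synthetic two-cell-type epigenome generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a genome tiled into contiguous unmethylated (U) and methylated (M)
segments, per-CpG bisulfite read counts that are beta-binomial around the
segment state, CpG islands that are GC- and CpG-enriched and biased toward
the U state, and histone-mark read tracks whose densities are log2-coupled
to the segment state with a configurable direction and effect size per mark.
Two cell types share one genome and one gene annotation; a configurable
fraction of segments flips state in cell 2, defining ground-truth
differentially methylated regions (DMRs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MarkSpec:
    """One histone-modification track.

    direction: 'active' marks are enriched in U segments, 'repressive' marks
    in M segments, 'null' marks are independent of state.  effect_size is the
    log2 ratio of mean read density between the preferred and non-preferred
    state; background_density is the geometric-mean density in reads per kb.
    """

    name: str
    direction: str = "null"  # {active, repressive, null}
    effect_size: float = 0.0
    background_density: float = 15.0

    def __post_init__(self):
        if self.direction not in ("active", "repressive", "null"):
            raise ConfigError(f"bad direction {self.direction!r} for mark {self.name}")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.direction == "null" and self.effect_size != 0:
            raise ConfigError("null marks must have effect_size 0")


def default_marks() -> list[MarkSpec]:
    """Sixteen-mark panel: a handful of informative active/repressive marks
    plus uninformative acetylation tracks, mimicking the redundancy of a
    real ChIP-seq compendium."""
    return [
        MarkSpec("H3K4me1", "active", 1.2),
        MarkSpec("H3K4me2", "active", 2.0),
        MarkSpec("H3K4me3", "active", 2.0),
        MarkSpec("H3K9ac", "active", 2.0),
        MarkSpec("H3K27ac", "active", 1.5),
        MarkSpec("H3K36me3", "repressive", 1.0),
        MarkSpec("H3K9me3", "repressive", 1.5),
        MarkSpec("H3K27me3", "repressive", 1.0),
        MarkSpec("H3K14ac"),
        MarkSpec("H3K18ac"),
        MarkSpec("H3K23ac"),
        MarkSpec("H3K4ac"),
        MarkSpec("H3K56ac"),
        MarkSpec("H4K8ac"),
        MarkSpec("H4K91ac"),
        MarkSpec("H2BK5ac"),
    ]


@dataclass(frozen=True)
class SyntheticConfig:
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 40
    cpg_island_rate: float = 8.0       # islands per Mb
    enhancer_rate: float = 5.0         # enhancers per Mb
    marks: tuple[MarkSpec, ...] = field(default_factory=lambda: tuple(default_marks()))
    segment_length_mean: int = 2_000   # bp, geometric
    u_fraction: float = 0.4            # P(U) for a segment outside islands, cell 1
    island_u_bias: float = 0.85        # P(U) for island-centred segments
    dmr_fraction: float = 0.1          # fraction of segments flipped in cell 2
    coverage_mean: float = 15.0        # Poisson mean reads per CpG
    beta_meth: tuple[float, float] = (8.0, 2.0)
    beta_unmeth: tuple[float, float] = (2.0, 8.0)
    read_length: int = 36
    seed: int = 0

    def __post_init__(self):
        for frac in (self.u_fraction, self.dmr_fraction, self.island_u_bias):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must lie in [0, 1]")
        if self.chrom_length < 10 * self.segment_length_mean:
            raise ConfigError("chrom_length must be >= 10 * segment_length_mean")
        if min(*self.beta_meth, *self.beta_unmeth) <= 0:
            raise ConfigError("beta parameters must be > 0")
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ConfigError("need at least one chromosome of positive length")
        names = [m.name for m in self.marks]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate mark names")

    @property
    def mark_names(self) -> list[str]:
        return [m.name for m in self.marks]

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}


@dataclass
class Genome:
    sequences: dict[str, str]
    genes: pd.DataFrame       # BED6: chrom, start, end, name, score, strand
    islands: pd.DataFrame     # BED3
    enhancers: pd.DataFrame   # BED3
    cpg_sites: dict[str, np.ndarray]  # 0-based positions of the C of each CpG

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass
class GroundTruth:
    """Planted state map.  `segments` has one row per segment with the state
    in each cell; flipped segments carry their DMR class (UM = U in cell 1,
    M in cell 2; MU the reverse)."""

    segments: pd.DataFrame  # chrom, start, end, state1, state2, is_dmr, dmr_class
    planted_ranking: list[str]

    def dmr_labels(self) -> pd.DataFrame:
        return self.segments.loc[self.segments["is_dmr"], ["chrom", "start", "end", "dmr_class"]]

    def to_json(self) -> dict:
        return {
            "segments": self.segments.to_dict(orient="list"),
            "planted_ranking": self.planted_ranking,
        }


@dataclass
class MarkReads:
    """One mark's simulated read track: sorted read-start arrays per chrom
    plus the emitted library size N (used for RPKM normalisation)."""

    name: str
    starts: dict[str, np.ndarray]
    read_length: int
    n_total: int

    def count_in(self, chrom: str, start: int, end: int) -> int:
        s = self.starts.get(chrom)
        if s is None:
            return 0
        return int(np.searchsorted(s, end, "left") - np.searchsorted(s, start, "left"))

    def to_bed(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"chrom": c, "start": s, "end": s + self.read_length})
            for c, s in self.starts.items()
        ]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=["chrom", "start", "end"])


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent streams so each generator stage is reproducible on its own
    return np.random.default_rng([int(config.seed), stream])


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng: np.random.Generator, n: int, gc: float = 0.40) -> np.ndarray:
    p_at = (1.0 - gc) / 2.0
    p_gc = gc / 2.0
    idx = rng.choice(4, size=n, p=[p_at, p_gc, p_gc, p_at])
    return _BASES[idx]


def _island_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    """CpG-island sequence built from a dinucleotide process: with
    probability 0.25 emit 'CG', otherwise one GC-rich base.  Regenerates on
    the (rare) draw that misses GC >= 0.5 or CpG O/E >= 0.6."""
    for _ in range(20):
        out = np.empty(n + 1, dtype="S1")
        i = 0
        emit_cg = rng.random(n) < 0.25
        single = _random_sequence(rng, n, gc=0.60)
        for j in range(n):
            if i >= n:
                break
            if emit_cg[j]:
                out[i] = b"C"
                out[i + 1] = b"G"
                i += 2
            else:
                out[i] = single[j]
                i += 1
        seq = out[:n]
        s = seq.tobytes().decode()
        n_c, n_g = s.count("C"), s.count("G")
        n_cpg = s.count("CG")
        if n == 0:
            return seq
        gc_ok = (n_c + n_g) / n >= 0.5
        oe_ok = n_c * n_g > 0 and (n_cpg * n) / (n_c * n_g) >= 0.6
        if gc_ok and oe_ok:
            return seq
    raise RuntimeError("failed to generate a qualifying CpG island")


def _place_intervals(
    rng: np.random.Generator, n: int, lengths: np.ndarray, chrom_len: int, min_gap: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Place n non-overlapping intervals uniformly; returns (starts, lengths)
    sorted by start with the pairing preserved."""
    starts: list[int] = []
    taken: list[tuple[int, int]] = []
    attempts = 0
    while len(starts) < n and attempts < 200 * max(n, 1):
        attempts += 1
        i = len(starts)
        s = int(rng.integers(0, max(1, chrom_len - int(lengths[i]))))
        e = s + int(lengths[i])
        if all(e + min_gap <= ts or s >= te + min_gap for ts, te in taken):
            starts.append(s)
            taken.append((s, e))
    if len(starts) < n:
        raise ConfigError("chromosome too short to place requested intervals")
    starts_arr = np.asarray(starts)
    order = np.argsort(starts_arr)
    return starts_arr[order], np.asarray(lengths)[:n][order]


def generate_genome(config: SyntheticConfig) -> Genome:
    """Build sequences, gene models, CpG islands and enhancers.

    Genes are separated by >= 3 kb so the 1.5 kb promoter/downstream windows
    of adjacent genes never collide at default settings.  CpG sites are the
    actual CG dinucleotides of the emitted sequence, thinned outside islands
    to roughly one per 50 bp (inside islands all CGs are retained, roughly
    one per 8-10 bp).
    """
    rng = _rng(config, 1)
    chroms = config.chrom_names()
    sequences: dict[str, str] = {}
    islands_rows = []
    enh_rows = []
    cpg_sites: dict[str, np.ndarray] = {}

    # distribute genes round-robin across chromosomes
    genes_per_chrom = {c: 0 for c in chroms}
    for i in range(config.n_genes):
        genes_per_chrom[chroms[i % len(chroms)]] += 1
    gene_rows = []

    for chrom in chroms:
        L = config.chrom_length
        seq = _random_sequence(rng, L)

        n_isl = int(round(config.cpg_island_rate * L / 1e6))
        if n_isl > 0:
            lens = rng.integers(500, 1501, size=n_isl)
            starts, lens = _place_intervals(rng, n_isl, lens, L, min_gap=200)
            for s, ln in zip(starts, lens):
                seq[s : s + int(ln)] = _island_sequence(rng, int(ln))
                islands_rows.append((chrom, int(s), int(s + ln)))

        n_enh = int(round(config.enhancer_rate * L / 1e6))
        for _ in range(n_enh):
            ln = int(rng.integers(200, 801))
            s = int(rng.integers(0, L - ln))
            enh_rows.append((chrom, s, s + ln))

        ng = genes_per_chrom[chrom]
        if ng > 0:
            glens = rng.integers(4000, 15001, size=ng)
            need = int(glens.sum()) + 3000 * (ng + 1)
            if need > L:
                raise ConfigError(
                    f"chromosome {chrom} ({L} bp) too short for {ng} genes (need {need} bp)"
                )
            slack = L - need
            extra = rng.multinomial(slack, np.full(ng + 1, 1.0 / (ng + 1)))
            pos = 0
            for gi in range(ng):
                pos += 3000 + int(extra[gi])
                start, end = pos, pos + int(glens[gi])
                strand = "+" if rng.random() < 0.5 else "-"
                gene_rows.append((chrom, start, end, f"gene_{chrom}_{gi + 1}", 0, strand))
                pos = end

        # CpG sites: every CG dinucleotide, thinned to ~1/50 bp outside islands
        arr = seq.view(np.uint8)
        cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        in_island = np.zeros(cg.shape, dtype=bool)
        for c, s, e in (r for r in islands_rows if r[0] == chrom):
            in_island |= (cg >= s) & (cg < e)
        keep = in_island | (rng.random(cg.shape) < 0.5)
        cpg_sites[chrom] = cg[keep].astype(np.int64)

        sequences[chrom] = seq.tobytes().decode()

    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    islands = pd.DataFrame(islands_rows, columns=["chrom", "start", "end"])
    enhancers = pd.DataFrame(enh_rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )
    return Genome(sequences, genes, islands, enhancers, cpg_sites)


def _segment_chrom(rng: np.random.Generator, L: int, mean_len: int) -> np.ndarray:
    """Segment boundaries 0 = b0 < b1 < ... < bk = L with geometric lengths."""
    n_guess = int(2.5 * L / mean_len) + 10
    lens = rng.geometric(1.0 / mean_len, size=n_guess)
    ends = np.cumsum(lens)
    ends = ends[ends < L]
    return np.concatenate([[0], ends, [L]]).astype(np.int64)


def generate_methylomes(
    config: SyntheticConfig, genome: Genome
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Tile the genome into alternating-state segments and emit per-CpG
    read counts for both cell types.

    Per CpG: total coverage ~ Poisson(coverage_mean), methylated count ~
    Binomial(coverage, level) with level ~ Beta(beta_meth) in M segments and
    Beta(beta_unmeth) in U segments, drawn independently per cell.  Cell 2
    shares cell 1's state map except at the planted flips.
    """
    rng = _rng(config, 2)
    seg_rows = []
    profiles: dict[int, list[pd.DataFrame]] = {1: [], 2: []}

    for chrom in config.chrom_names():
        L = len(genome.sequences[chrom])
        bounds = _segment_chrom(rng, L, config.segment_length_mean)
        starts, ends = bounds[:-1], bounds[1:]
        mids = (starts + ends) // 2

        isl = genome.islands[genome.islands["chrom"] == chrom]
        in_island = np.zeros(len(starts), dtype=bool)
        if len(isl):
            isl_starts = isl["start"].to_numpy()
            isl_ends = isl["end"].to_numpy()
            idx = np.searchsorted(isl_starts, mids, "right") - 1
            ok = idx >= 0
            in_island[ok] = mids[ok] < isl_ends[idx[ok]]

        p_u = np.where(in_island, config.island_u_bias, config.u_fraction)
        state1 = np.where(rng.random(len(starts)) < p_u, "U", "M")
        flip = rng.random(len(starts)) < config.dmr_fraction
        state2 = state1.copy()
        state2[flip] = np.where(state1[flip] == "U", "M", "U")
        dmr_class = np.where(flip, np.where(state1 == "U", "UM", "MU"), "")

        for s, e, s1, s2, f, dc in zip(starts, ends, state1, state2, flip, dmr_class):
            seg_rows.append((chrom, int(s), int(e), s1, s2, bool(f), dc))

        pos = genome.cpg_sites[chrom]
        seg_idx = np.searchsorted(ends, pos, "right")
        for cell, states in ((1, state1), (2, state2)):
            cpg_state = states[seg_idx]
            a = np.where(cpg_state == "M", config.beta_meth[0], config.beta_unmeth[0])
            b = np.where(cpg_state == "M", config.beta_meth[1], config.beta_unmeth[1])
            level = rng.beta(a, b)
            cov = rng.poisson(config.coverage_mean, size=pos.shape)
            meth = rng.binomial(cov, level)
            covered = cov > 0
            profiles[cell].append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos[covered],
                        "count_methylated": meth[covered],
                        "count_total": cov[covered],
                    }
                )
            )

    segments = pd.DataFrame(
        seg_rows, columns=["chrom", "start", "end", "state1", "state2", "is_dmr", "dmr_class"]
    )
    ranking = [m.name for m in sorted(config.marks, key=lambda m: -m.effect_size)]
    gt = GroundTruth(segments=segments, planted_ranking=ranking)
    prof1 = pd.concat(profiles[1], ignore_index=True)
    prof2 = pd.concat(profiles[2], ignore_index=True)
    return prof1, prof2, gt


def generate_mark_reads(
    config: SyntheticConfig, ground_truth: GroundTruth, cell: int = 1
) -> dict[str, MarkReads]:
    """Emit fixed-length read tracks for every mark in `config.marks`.

    Per segment the read count is Poisson(density * length_kb) with
    density = background_density * 2**(+effect_size/2) in the mark's
    preferred state and 2**(-effect_size/2) otherwise; null marks sit at the
    background everywhere.  Reads are placed uniformly within their segment.
    """
    if cell not in (1, 2):
        raise ConfigError("cell must be 1 or 2")
    state_col = f"state{cell}"
    segs = ground_truth.segments
    out: dict[str, MarkReads] = {}
    for mi, mark in enumerate(config.marks):
        rng = _rng(config, 1000 + 10 * mi + cell)
        starts: dict[str, np.ndarray] = {}
        total = 0
        preferred = "U" if mark.direction == "active" else "M"
        for chrom, grp in segs.groupby("chrom", sort=True):
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            st = grp[state_col].to_numpy()
            if mark.direction == "null":
                dens = np.full(len(grp), mark.background_density)
            else:
                shift = np.where(st == preferred, mark.effect_size / 2.0, -mark.effect_size / 2.0)
                dens = mark.background_density * np.exp2(shift)
            counts = rng.poisson(dens * (e - s) / 1000.0)
            reads = []
            for si in np.flatnonzero(counts):
                hi = max(s[si] + 1, e[si] - config.read_length)
                reads.append(rng.integers(s[si], hi, size=counts[si]))
            arr = np.sort(np.concatenate(reads)) if reads else np.empty(0, dtype=np.int64)
            starts[chrom] = arr.astype(np.int64)
            total += int(arr.size)
        out[mark.name] = MarkReads(mark.name, starts, config.read_length, total)
    return out
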