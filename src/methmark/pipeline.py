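"""End-to-end orchestration: synthetic bundle -> annotation -> pattern
calling -> features -> classification -> DMRs -> effector tests -> DMR
prediction -> co-variation, with one master seed driving every stage.

Per-stage seeds are derived from the master seed by hashing the stage name
(CRC32 xor master, mod 2**31), so no two stages share a random stream and
re-running a single stage from persisted intermediates reproduces the full
run.  All tables are TSV with a header comment recording the config hash
and package version; the run report is a sorted-key JSON file.  A fixed
master seed therefore makes the whole output bundle byte-identical across
runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .annotation import (
    CATEGORIES,
    build_region_map,
    classify_regions,
    genes_from_bed,
    overlay_cpg_islands,
)
from .classify import ModelParams, compare_feature_sets, crossval, cumulative_curve, essential_features, rank_importance
from .covariation import map_to_genes, overlap_enrichment, select_covariation
from .dmr import informative_effectors, predict_dmr_patterns
from .features import SEQ_FEATURES, feature_matrix, log2_fold_change, mean_signal_matrix, cluster_signatures, rpkm_signal
from .patterns import PatternParams, call_dmrs, call_patterns, pattern_distribution
from .synthetic import SyntheticConfig, generate_genome, generate_mark_reads, generate_methylomes

logger = logging.getLogger(__name__)

GENE_CATEGORIES = ("promoter", "gene_body", "downstream")


def stage_seed(master_seed: int, stage: str) -> int:
    return (zlib.crc32(stage.encode()) ^ int(master_seed)) % 2**31


@dataclass
class RunConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    patterns: PatternParams = field(default_factory=PatternParams)
    model: ModelParams = field(default_factory=lambda: ModelParams(n_estimators=200))
    n_repeats: int = 10
    n_folds: int = 10
    essential_k: int = 6
    alpha: float = 0.001
    min_frac: float = 0.0
    categories: tuple[str, ...] = CATEGORIES
    include_cpg_island: bool = True
    effector_candidates: str = "essential_union"  # or "all"
    # cell 1 is classified in every scope; other cells only in these (their
    # genome-wide essential set is what the DMR stage consumes)
    secondary_cell_scopes: tuple[str, ...] = ("whole_genome",)
    quantile_rule: str = "literal"
    master_seed: int = 0
    gmt_path: str | None = None

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (tuple, list)):
                return [enc(x) for x in o]
            if callable(o):
                return repr(o)
            return o

        blob = json.dumps(enc(self), sort_keys=True, default=repr).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# methmark {__version__} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _scope_mask(features_df: pd.DataFrame, scope: str) -> np.ndarray:
    if scope == "whole_genome":
        return np.ones(len(features_df), dtype=bool)
    if scope == "cpg_island":
        return features_df["cpg_island"].to_numpy(dtype=bool)
    return (features_df["category"] == scope).to_numpy()


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline into `outdir`; returns the report dict
    (also written as report.json).  A stage failure raises StageError naming
    the stage; outputs of completed stages are retained."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    report: dict = {"version": __version__, "config_hash": cfg_hash, "master_seed": config.master_seed}
    stage = "synth"
    try:
        syn = dataclasses.replace(config.synthetic, seed=stage_seed(config.master_seed, "synth"))
        genome = generate_genome(syn)
        prof1, prof2, gt = generate_methylomes(syn, genome)
        marks1 = generate_mark_reads(syn, gt, cell=1)
        marks2 = generate_mark_reads(syn, gt, cell=2)
        io.write_fasta(genome.sequences, outdir / "genome.fa")
        io.write_bed(genome.genes, outdir / "genes.bed")
        io.write_bed(genome.islands, outdir / "cpg_islands.bed")
        io.write_bed(genome.enhancers, outdir / "enhancers.bed")
        io.write_coverage(prof1, outdir / "cell1.cov.tsv")
        io.write_coverage(prof2, outdir / "cell2.cov.tsv")
        for cell, marks in ((1, marks1), (2, marks2)):
            for name, track in marks.items():
                io.write_bed(track.to_bed(), outdir / f"cell{cell}.{name}.reads.bed")
        io.write_json(gt.to_json(), outdir / "ground_truth.json")
        mark_names = syn.mark_names

        stage = "annotate"
        region_map = build_region_map(genes_from_bed(genome.genes), genome.chrom_sizes())
        category_bed = region_map.to_frame()
        io.write_bed(category_bed, outdir / "category_map.bed")

        stage = "call-patterns"
        regions = {}
        for cell, prof in ((1, prof1), (2, prof2)):
            reg = call_patterns(prof, config.patterns)
            reg["category"] = classify_regions(reg, region_map)
            reg["cpg_island"] = overlay_cpg_islands(reg, genome.islands)
            regions[cell] = reg
            out = reg.copy()
            out["name"] = out.pop("pattern")
            out["score"] = (1000 * out["mean_level"]).round().astype(int)
            io.write_bed(out[["chrom", "start", "end", "name", "score"]], outdir / f"cell{cell}.regions.bed")
        counts, props, chi2, chi2_p = pattern_distribution(regions[1])
        report["pattern_counts_cell1"] = {
            p: {c: int(counts.loc[p, c]) for c in counts.columns} for p in counts.index
        }
        report["pattern_chi2"] = {"statistic": chi2, "p_value": chi2_p}

        stage = "features"
        feats = {}
        for cell, marks in ((1, marks1), (2, marks2)):
            fm = feature_matrix(regions[cell], genome.sequences, marks)
            feats[cell] = fm
            _write_tsv(fm, outdir / f"cell{cell}.features.tsv", cfg_hash)
        sig = mean_signal_matrix(
            pd.concat(
                [feats[1].assign(cell="cell1"), feats[2].assign(cell="cell2")], ignore_index=True
            ),
            mark_names,
            ["cell", "pattern", "category"],
        )
        _, leaf_order = cluster_signatures(sig)
        report["signature_cluster_leaves"] = ["|".join(map(str, k)) for k in leaf_order]

        stage = "classify"
        scopes = ["whole_genome"] + [c for c in config.categories]
        if config.include_cpg_island:
            scopes.append("cpg_island")
        feature_names = mark_names + list(SEQ_FEATURES)
        classify_report: dict = {}
        essential_marks: dict[int, list[str]] = {}
        for cell in (1, 2):
            fm = feats[cell]
            y_all = (fm["pattern"] == "M").to_numpy(dtype=int)
            cell_key = f"cell{cell}"
            classify_report[cell_key] = {}
            cell_scopes = scopes if cell == 1 else [s for s in scopes if s in config.secondary_cell_scopes]
            for scope in cell_scopes:
                mask = _scope_mask(fm, scope)
                y = y_all[mask]
                if min((y == 1).sum(), (y == 0).sum()) < config.n_folds:
                    classify_report[cell_key][scope] = {"skipped": "too few regions per class"}
                    continue
                seed = stage_seed(config.master_seed, f"classify/{cell}/{scope}")
                sub = fm.loc[mask].reset_index(drop=True)
                comp = compare_feature_sets(
                    sub, y, mark_names, model_params=config.model,
                    n_repeats=config.n_repeats, n_folds=config.n_folds, seed=seed,
                )
                ranking = rank_importance(
                    sub, y, feature_names, config.model, n_repeats=config.n_repeats, seed=seed
                )
                if scope == "whole_genome":
                    curve = cumulative_curve(
                        sub, y, ranking, config.model,
                        n_repeats=config.n_repeats, n_folds=config.n_folds, seed=seed,
                    )
                    _write_tsv(curve, outdir / f"{cell_key}.{scope}.curve.tsv", cfg_hash)
                    ess = essential_features(curve, ranking, k=config.essential_k)
                else:
                    top_k = list(ranking["feature"].iloc[: config.essential_k])
                    auc_k = crossval(
                        sub, y, top_k, config.model, config.n_repeats, config.n_folds, seed=seed
                    ).mean_auc
                    ess = {"features": top_k, "k": config.essential_k, "mean_auc": auc_k}
                _write_tsv(ranking, outdir / f"{cell_key}.{scope}.importance.tsv", cfg_hash)
                classify_report[cell_key][scope] = {
                    "auc": {name: res.mean_auc for name, res in comp.items()},
                    "acc": {name: res.mean_acc for name, res in comp.items()},
                    "importance_rank": list(ranking["feature"]),
                    "essential": ess,
                }
                if scope == "whole_genome":
                    essential_marks[cell] = [f for f in ess["features"] if f in mark_names]
        report["classification"] = classify_report

        stage = "call-dmrs"
        dmrs = call_dmrs(regions[1], regions[2], min_frac=config.min_frac)
        if len(dmrs):
            dmrs["category"] = classify_regions(dmrs, region_map)
            dmrs["cpg_island"] = overlay_cpg_islands(dmrs, genome.islands)
            for name in mark_names:
                fc = np.empty(len(dmrs))
                for i, r in enumerate(dmrs.itertuples(index=False)):
                    ln = int(r.end) - int(r.start)
                    s1 = rpkm_signal(marks1[name].count_in(r.chrom, int(r.start), int(r.end)), ln, marks1[name].n_total)
                    s2 = rpkm_signal(marks2[name].count_in(r.chrom, int(r.start), int(r.end)), ln, marks2[name].n_total)
                    fc[i] = log2_fold_change(s1, s2)
                dmrs[name] = fc
            _write_tsv(dmrs, outdir / "dmrs.tsv", cfg_hash)
        report["dmr_counts"] = {
            cls: int((dmrs["dmr_class"] == cls).sum()) if len(dmrs) else 0 for cls in ("UM", "MU")
        }

        stage = "dmr-predict"
        if config.effector_candidates == "all" or not essential_marks:
            candidates = list(mark_names)
        else:
            union = set(essential_marks.get(1, [])) | set(essential_marks.get(2, []))
            candidates = [m for m in mark_names if m in union] or list(mark_names)
        dmr_report: dict = {"effector_candidates": candidates}
        for scope in ["whole_genome"] + list(GENE_CATEGORIES) + ["intergenic"]:
            if not len(dmrs):
                dmr_report[scope] = {"skipped": "no DMRs"}
                continue
            mask = _scope_mask(dmrs, scope)
            sub = dmrs.loc[mask].reset_index(drop=True)
            n_um = int((sub["dmr_class"] == "UM").sum())
            n_mu = int((sub["dmr_class"] == "MU").sum())
            if min(n_um, n_mu) < max(config.n_folds, 5):
                dmr_report[scope] = {"skipped": f"too few DMRs per class (UM={n_um}, MU={n_mu})"}
                continue
            eff = informative_effectors(sub, candidates, alpha=config.alpha)
            _write_tsv(eff, outdir / f"effectors.{scope}.tsv", cfg_hash)
            informative = list(eff.loc[eff["informative"], "mark"])
            entry = {
                "n_um": n_um,
                "n_mu": n_mu,
                "informative": informative,
            }
            if informative:
                seed = stage_seed(config.master_seed, f"dmr-predict/{scope}")
                res = predict_dmr_patterns(
                    sub, informative, config.model, config.n_repeats, config.n_folds, seed=seed
                )
                entry["auc"] = res.mean_auc
                entry["acc"] = res.mean_acc
            dmr_report[scope] = entry
        report["dmr_analysis"] = dmr_report

        stage = "covariation"
        gene_models = genes_from_bed(genome.genes)
        covar_report: dict = {}
        if len(dmrs):
            sel = select_covariation(dmrs, quantile_rule=config.quantile_rule)
            covar_report["n_covar1"] = int(len(sel.covar1))
            covar_report["n_covar2"] = int(len(sel.covar2))
            for label, cdf in (("covar1", sel.covar1), ("covar2", sel.covar2)):
                for cat, short in zip(GENE_CATEGORIES, ("PG", "GG", "DG")):
                    genes_hit = map_to_genes(cdf[cdf["category"] == cat], gene_models, cat)
                    covar_report[f"{label}_{short}"] = genes_hit
                    with open(outdir / f"{label}.{short}.genes.txt", "w") as fh:
                        fh.write("\n".join(genes_hit) + ("\n" if genes_hit else ""))
        # enhancer overlap: intergenic enhancers vs newly unmethylated regions
        new_u = _difference_regions(
            regions[2][regions[2]["pattern"] == "U"], regions[1][regions[1]["pattern"] == "U"]
        )
        intergenic = category_bed[category_bed["name"] == "intergenic"]
        if len(genome.enhancers):
            covar_report["enhancer_overlap"] = overlap_enrichment(new_u, intergenic, genome.enhancers)
        report["covariation"] = covar_report
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(stage, exc) from exc

    io.write_json(report, outdir / "report.json")
    return report


def _difference_regions(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Rows of `a` that do not overlap any interval of `b`."""
    from .covariation import _overlaps_any

    if len(a) == 0:
        return a
    return a.loc[~_overlaps_any(a, b)]


def validate_inputs(paths: dict[str, str | Path], chrom_sizes: dict[str, int] | None = None) -> list[str]:
    """Sanity checks over an input bundle; returns itemized diagnostics
    (empty list = clean).  Recognized keys: 'genes', 'islands', 'enhancers'
    (BED), 'coverage' or 'coverage1'/'coverage2' (per-CpG tables), and
    'mark:<name>' read BEDs."""
    diags: list[str] = []
    for key, path in paths.items():
        path = Path(path)
        if not path.exists():
            diags.append(f"{key}: file not found: {path}")
            continue
        if key.startswith(("genes", "islands", "enhancers", "mark:")):
            try:
                bed = io.read_bed(path)
            except Exception as exc:  # noqa: BLE001
                diags.append(f"{key}: unreadable BED ({exc})")
                continue
            for chrom, grp in bed.groupby("chrom"):
                if not grp["start"].is_monotonic_increasing:
                    diags.append(f"{key}: intervals not sorted by start on {chrom}")
                if (grp["start"] < 0).any() or (grp["end"] <= grp["start"]).any():
                    diags.append(f"{key}: invalid interval coordinates on {chrom}")
                if chrom_sizes is not None:
                    if chrom not in chrom_sizes:
                        diags.append(f"{key}: unknown chromosome {chrom}")
                    elif (grp["end"] > chrom_sizes[chrom]).any():
                        diags.append(f"{key}: interval beyond {chrom} size")
        elif key.startswith("coverage"):
            try:
                cov = io.read_coverage(path)
            except Exception as exc:  # noqa: BLE001
                diags.append(f"{key}: unreadable coverage table ({exc})")
                continue
            for chrom, grp in cov.groupby("chrom"):
                if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                    diags.append(f"{key}: positions not strictly increasing on {chrom}")
                if chrom_sizes is not None and chrom in chrom_sizes:
                    if (grp["pos"] >= chrom_sizes[chrom]).any():
                        diags.append(f"{key}: position beyond {chrom} size")
            if (cov["count_methylated"] > cov["count_total"]).any():
                diags.append(f"{key}: methylated count exceeds total")
    return diags
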