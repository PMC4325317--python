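import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import methmark as mm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def brute_force_caller(pos, meth, total, params):
    """Independent linear-scan oracle for the U/M region caller."""
    regions = []
    run = []  # list of (pos, level, state)
    def flush():
        if len(run) >= params.min_cpg and run[0][2] in ("U", "M"):
            levels = [lv for _, lv, _ in run]
            regions.append(
                (run[0][0], run[-1][0] + 1, run[0][2], len(run), sum(levels) / len(levels))
            )
    for p, m, t in zip(pos, meth, total):
        if t < max(params.min_coverage, 1):
            continue
        lv = m / t
        if lv <= params.u_max:
            st = "U"
        elif lv >= params.m_min:
            st = "M"
        else:
            st = "-"
        if run and (st != run[-1][2] or p - run[-1][0] > params.max_gap):
            flush()
            run = []
        run.append((p, lv, st))
    flush()
    return regions


def trapezoid_auc(y, scores):
    """Brute-force ROC AUC: sweep every distinct score threshold, trapezoid
    integrate TPR over FPR."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    fpr, tpr = [], []
    for t in thresholds:
        pred = scores >= t
        tpr.append((pred & (y == 1)).sum() / n_pos)
        fpr.append((pred & (y == 0)).sum() / n_neg)
    return float(np.trapezoid(tpr, fpr))


@pytest.fixture(scope="session")
def default_bundle():
    """Default-design synthetic bundle at desk scale: 16-mark panel, two
    chromosomes, with regions, categories and the cell-1 feature matrix."""
    cfg = mm.SyntheticConfig(n_chroms=2, chrom_length=350_000, n_genes=16, seed=20)
    genome = mm.generate_genome(cfg)
    prof1, prof2, gt = mm.generate_methylomes(cfg, genome)
    marks1 = mm.generate_mark_reads(cfg, gt, cell=1)
    regions = mm.call_patterns(prof1)
    rmap = mm.build_region_map(
        [mm.GeneModel(r["name"], r["chrom"], r["start"], r["end"], r["strand"]) for _, r in genome.genes.iterrows()],
        genome.chrom_sizes(),
    )
    regions["category"] = mm.classify_regions(regions, rmap)
    regions["cpg_island"] = mm.overlay_cpg_islands(regions, genome.islands)
    fm = mm.feature_matrix(regions, genome.sequences, marks1)
    return {
        "config": cfg,
        "genome": genome,
        "prof1": prof1,
        "prof2": prof2,
        "gt": gt,
        "marks1": marks1,
        "regions": regions,
        "region_map": rmap,
        "features": fm,
    }


def random_profile(rng, n=200, chrom="chr1"):
    pos = np.cumsum(rng.integers(2, 400, size=n))
    total = rng.integers(0, 40, size=n)
    meth = rng.binomial(total, rng.random(n))
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "count_methylated": meth, "count_total": total}
    )
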