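"""Co-variation gene-set selection and generic hypergeometric enrichment.

Co-var1 is the set of U->M DMRs whose H3K4me2 and H3K4me3 fold changes are
both below their class-wise three-quarters quantile; Co-var2 the M->U DMRs
with both fold changes above their class-wise one-quarter quantile
(quantiles by linear interpolation between order statistics).  DMRs map to
genes through the gene-region window (promoter, gene body or downstream)
that contains the DMR midpoint.  Enrichment of the resulting gene lists
against user-supplied annotation sets, and of region overlaps, uses the
one-sided hypergeometric tail with Benjamini-Hochberg adjustment across
sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneModel

logger = logging.getLogger(__name__)


@dataclass
class CoVarSelection:
    covar1: pd.DataFrame  # U->M DMRs passing the quantile rule
    covar2: pd.DataFrame  # M->U DMRs passing the quantile rule


def select_covariation(
    dmrs: pd.DataFrame,
    k4me2_col: str = "H3K4me2",
    k4me3_col: str = "H3K4me3",
    class_col: str = "dmr_class",
    quantile_rule: str = "literal",
) -> CoVarSelection:
    """Quantile selection of co-varying DMRs.

    quantile_rule='literal' applies the printed rule (< Q3 within U->M for
    decreases, > Q1 within M->U for increases); 'strict' tightens the cuts
    to < Q1 and > Q3 respectively.
    """
    if quantile_rule not in ("literal", "strict"):
        raise ValueError("quantile_rule must be 'literal' or 'strict'")
    q_dec, q_inc = (0.75, 0.25) if quantile_rule == "literal" else (0.25, 0.75)

    um = dmrs[dmrs[class_col] == "UM"]
    mu = dmrs[dmrs[class_col] == "MU"]
    if len(um) == 0:
        logger.warning("no U->M DMRs; Co-var1 is empty")
        covar1 = um
    else:
        t2 = np.quantile(um[k4me2_col], q_dec)
        t3 = np.quantile(um[k4me3_col], q_dec)
        covar1 = um[(um[k4me2_col] < t2) & (um[k4me3_col] < t3)]
    if len(mu) == 0:
        logger.warning("no M->U DMRs; Co-var2 is empty")
        covar2 = mu
    else:
        t2 = np.quantile(mu[k4me2_col], q_inc)
        t3 = np.quantile(mu[k4me3_col], q_inc)
        covar2 = mu[(mu[k4me2_col] > t2) & (mu[k4me3_col] > t3)]
    return CoVarSelection(covar1.copy(), covar2.copy())


def map_to_genes(dmrs: pd.DataFrame, genes: list[GeneModel], category: str) -> list[str]:
    """Deduplicated, sorted ids of genes whose `category` window (promoter,
    gene_body or downstream) contains a DMR midpoint."""
    if category not in ("promoter", "gene_body", "downstream"):
        raise ValueError(f"category must be a gene-anchored window, got {category!r}")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        s, e = g.windows()[category]
        if e > s:
            trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g.id)
    hits: set[str] = set()
    for r in dmrs.itertuples(index=False):
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        mid = (int(r.start) + int(r.end)) // 2
        for iv in tree.at(mid):
            hits.add(iv.data)
    return sorted(hits)


def hypergeom_tail(k: int, big_n: int, big_k: int, n: int) -> float:
    """One-sided P(X >= k) with population size big_n, big_k successes and
    n draws."""
    return float(stats.hypergeom.sf(k - 1, big_n, big_k, n))


def geneset_enrichment(
    study: set[str], background: set[str], annotation_sets: dict[str, set[str]]
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a study gene list within a
    background population, Benjamini-Hochberg-adjusted across sets."""
    if len(background) == 0:
        raise ValueError("background gene set is empty")
    if not study <= background:
        raise ValueError("study genes must be a subset of the background")
    big_n = len(background)
    n = len(study)
    rows = []
    for name, genes in annotation_sets.items():
        members = genes & background
        k = len(study & members)
        p = hypergeom_tail(k, big_n, len(members), n)
        rows.append((name, k, len(members), p))
    out = pd.DataFrame(rows, columns=["set", "k", "set_size", "p_value"])
    if len(out):
        _, q, _, _ = multipletests(out["p_value"], method="fdr_bh")
        out["q_value"] = q
    return out.sort_values("p_value", kind="stable", ignore_index=True)


def _overlaps_any(universe: pd.DataFrame, other: pd.DataFrame) -> np.ndarray:
    """Boolean per universe row: any base-pair overlap with `other`."""
    flags = np.zeros(len(universe), dtype=bool)
    for chrom, grp in other.groupby("chrom"):
        sel = (universe["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        o = grp.sort_values("start")
        os_, oe = o["start"].to_numpy(), o["end"].to_numpy()
        us = universe.loc[sel, "start"].to_numpy()
        ue = universe.loc[sel, "end"].to_numpy()
        # overlap iff some other-interval starts before ue and ends after us
        i = np.searchsorted(os_, ue, "left")  # first interval starting at/after ue
        hit = np.zeros(us.shape, dtype=bool)
        # check intervals before index i for an end beyond us: use running max of ends
        run_max = np.maximum.accumulate(oe)
        ok = i > 0
        hit[ok] = run_max[i[ok] - 1] > us[ok]
        flags[np.flatnonzero(sel)] = hit
    return flags


def overlap_enrichment(
    query: pd.DataFrame, target: pd.DataFrame, universe: pd.DataFrame
) -> dict:
    """Hypergeometric enrichment of query/target co-occurrence over a
    universe of regions.

    Universe elements are the population; those overlapping the target set
    are the successes, those overlapping the query are the draws.  Reports
    the fraction of target-overlapping universe elements that also overlap
    the query, and the one-sided tail p-value.
    """
    if len(universe) == 0:
        raise ValueError("universe region set is empty")
    in_query = _overlaps_any(universe, query)
    in_target = _overlaps_any(universe, target)
    big_n = len(universe)
    big_k = int(in_target.sum())
    n = int(in_query.sum())
    k = int((in_query & in_target).sum())
    fraction = k / big_k if big_k else 0.0
    p = hypergeom_tail(k, big_n, big_k, n)
    return {"N": big_n, "K": big_k, "n": n, "k": k, "fraction": fraction, "p_value": p}
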