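"""Informative-effector selection and DMR class prediction.

For each histone mark, the per-DMR log2 fold change (cell 2 over cell 1) is
compared between the U->M and M->U classes with a two-sided Wilcoxon
rank-sum test; marks with p below `alpha` (default 0.001, uncorrected by
default, mirroring a raw significance cut) are the informative effectors.
Those effectors' fold changes then feed the balanced repeated-CV classifier
with U->M as the positive class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import CVResult, ModelParams, crossval


def ranksum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both groups have <= 20
    observations and no ties; otherwise the normal approximation with tie
    correction (no continuity correction, so small-sample tail rates track
    the nominal level).  Returns (rank-sum statistic W of the first sample,
    p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need >= 2 observations per group")
    has_ties = len(np.unique(np.concatenate([x, y]))) < nx + ny
    method = "exact" if (nx <= 20 and ny <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=False)
    w = float(res.statistic) + nx * (nx + 1) / 2.0  # U -> rank-sum of sample x
    return w, float(res.pvalue)


def informative_effectors(
    dmr_features: pd.DataFrame,
    mark_names: list[str],
    alpha: float = 0.001,
    class_col: str = "dmr_class",
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-mark rank-sum test of fold changes, U->M vs M->U.

    `dmr_features` holds one row per DMR with the class column and one
    fold-change column per mark.  `correction='fdr_bh'` optionally replaces
    the raw p-value cut with a Benjamini-Hochberg one."""
    um = dmr_features[dmr_features[class_col] == "UM"]
    mu = dmr_features[dmr_features[class_col] == "MU"]
    if len(um) < 2 or len(mu) < 2:
        missing = "UM" if len(um) < 2 else "MU"
        raise ValueError(f"need >= 2 DMRs per class; class {missing} is too small")
    rows = []
    for mark in mark_names:
        w, p = ranksum_test(um[mark].to_numpy(), mu[mark].to_numpy())
        rows.append((mark, w, p))
    out = pd.DataFrame(rows, columns=["mark", "statistic", "p_value"])
    if correction is not None:
        reject, qvals, _, _ = multipletests(out["p_value"], alpha=alpha, method=correction)
        out["q_value"] = qvals
        out["informative"] = reject
    else:
        out["informative"] = out["p_value"] < alpha
    return out


def predict_dmr_patterns(
    dmr_features: pd.DataFrame,
    effectors: list[str],
    model_params: ModelParams | None = None,
    n_repeats: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    class_col: str = "dmr_class",
) -> CVResult:
    """Balanced repeated-CV prediction of U->M (positive) vs M->U (negative)
    from the informative effectors' fold changes."""
    if not effectors:
        raise ValueError("effector set is empty")
    classes = set(dmr_features[class_col])
    if not {"UM", "MU"} <= classes:
        raise ValueError(f"both DMR classes required, found {sorted(classes)}")
    y = (dmr_features[class_col] == "UM").to_numpy(dtype=int)
    return crossval(
        dmr_features, y, list(effectors), model_params, n_repeats, n_folds, seed=seed
    )
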