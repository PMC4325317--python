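"""Balanced-sampling, repeated cross-validated prediction of methylation
patterns, with mean-decrease-Gini feature importance, cumulative top-n
feature curves and essential-feature extraction.

Protocol: for each of `n_repeats` sampling repeats a fresh class-balanced
sample is drawn (majority class downsampled without replacement to the
minority size), stratified k-fold cross-validation is run with an ensemble
of impurity-split decision trees (a random forest), and the AUC is computed
from the pooled out-of-fold class probabilities of that repeat.  ACC,
sensitivity (SE, true-positive rate) and specificity (SP) are taken at the
0.5 probability threshold.  Reported metrics are arithmetic means over
repeats.  Feature importance is the forest's total Gini-impurity decrease
attributable to each feature, averaged over the sampling repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

SEED_MOD = 2**31


@dataclass(frozen=True)
class ModelParams:
    """Ensemble-tree settings.  Any scikit-learn classifier exposing
    fit / predict_proba / feature_importances_ can be plugged in through
    `factory`; the shipped default is a Gini random forest."""

    n_estimators: int = 500
    max_features: str | float = "sqrt"
    factory: object = None

    def build(self, seed: int):
        if self.factory is not None:
            return self.factory(seed)
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            criterion="gini",
            max_features=self.max_features,
            random_state=int(seed),
            n_jobs=1,
        )


@dataclass
class CVResult:
    feature_subset: list[str]
    per_repeat: pd.DataFrame  # columns: repeat, auc, acc, se, sp
    roc_points: pd.DataFrame  # columns: fpr, tpr (vertically averaged)

    @property
    def mean_auc(self) -> float:
        return float(self.per_repeat["auc"].mean())

    @property
    def mean_acc(self) -> float:
        return float(self.per_repeat["acc"].mean())

    @property
    def mean_se(self) -> float:
        return float(self.per_repeat["se"].mean())

    @property
    def mean_sp(self) -> float:
        return float(self.per_repeat["sp"].mean())

    def summary(self) -> dict:
        return {
            "features": list(self.feature_subset),
            "mean_auc": self.mean_auc,
            "mean_acc": self.mean_acc,
            "mean_se": self.mean_se,
            "mean_sp": self.mean_sp,
        }


def balanced_sample(
    pos_idx: np.ndarray, neg_idx: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Indices of a class-balanced dataset: the minority class is taken
    whole, the majority class downsampled without replacement to match."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos_idx = np.asarray(pos_idx)
    neg_idx = np.asarray(neg_idx)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both classes must be non-empty")
    k = min(len(pos_idx), len(neg_idx))
    pos = rng.choice(pos_idx, size=k, replace=False) if len(pos_idx) > k else pos_idx.copy()
    neg = rng.choice(neg_idx, size=k, replace=False) if len(neg_idx) > k else neg_idx.copy()
    out = np.concatenate([pos, neg])
    rng.shuffle(out)
    return out


def pooled_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC of pooled scores (the quantity each CV repeat reports)."""
    return float(roc_auc_score(y_true, scores))


def _metrics(y_true: np.ndarray, prob: np.ndarray) -> tuple[float, float, float, float]:
    pred = prob >= 0.5
    pos = y_true == 1
    auc = pooled_auc(y_true, prob)
    acc = float(np.mean(pred == pos))
    se = float(np.mean(pred[pos])) if pos.any() else np.nan
    sp = float(np.mean(~pred[~pos])) if (~pos).any() else np.nan
    return auc, acc, se, sp


_ROC_GRID = np.linspace(0.0, 1.0, 101)


def crossval(
    X: pd.DataFrame,
    y: np.ndarray,
    feature_subset: list[str],
    model_params: ModelParams | None = None,
    n_repeats: int = 10,
    n_folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated balanced stratified cross-validation on a labelled feature
    table.  `y` is 0/1 with 1 the positive class; the table may be
    unbalanced — each repeat draws its own balanced sample."""
    model_params = model_params or ModelParams()
    y = np.asarray(y, dtype=int)
    Xs = X[list(feature_subset)].to_numpy(dtype=float)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both classes must be present")
    if 2 * min(len(pos_idx), len(neg_idx)) < 2 * n_folds:
        raise ValueError(
            f"balanced dataset of {2 * min(len(pos_idx), len(neg_idx))} items is too small "
            f"for {n_folds}-fold CV"
        )
    master = np.random.default_rng(seed)
    repeat_seeds = master.integers(0, SEED_MOD, size=n_repeats)
    rows = []
    tprs = []
    for rep, rep_seed in enumerate(repeat_seeds):
        rng = np.random.default_rng(int(rep_seed))
        idx = balanced_sample(pos_idx, neg_idx, rng)
        Xr, yr = Xs[idx], y[idx]
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rep_seed))
        prob = np.empty(len(yr))
        for fold_i, (tr, te) in enumerate(skf.split(Xr, yr)):
            clf = model_params.build(int(rep_seed) + fold_i)
            clf.fit(Xr[tr], yr[tr])
            pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
            prob[te] = clf.predict_proba(Xr[te])[:, pos_col]
        auc, acc, se, sp = _metrics(yr, prob)
        rows.append((rep, auc, acc, se, sp))
        fpr, tpr, _ = roc_curve(yr, prob)
        tprs.append(np.interp(_ROC_GRID, fpr, tpr))
    per_repeat = pd.DataFrame(rows, columns=["repeat", "auc", "acc", "se", "sp"])
    roc_points = pd.DataFrame({"fpr": _ROC_GRID, "tpr": np.mean(tprs, axis=0)})
    return CVResult(list(feature_subset), per_repeat, roc_points)


def compare_feature_sets(
    X: pd.DataFrame,
    y: np.ndarray,
    mark_names: list[str],
    seq_names: tuple[str, str] = ("gc_content", "cpg_oe"),
    model_params: ModelParams | None = None,
    n_repeats: int = 10,
    n_folds: int = 10,
    seed: int = 0,
) -> dict[str, CVResult]:
    """CVResults for sequence features (SF), histone marks (HM) and their
    combination (HM+SF), on identical sampling repeats (shared seed) so that
    differences reflect the feature sets only."""
    subsets = {
        "SF": list(seq_names),
        "HM": list(mark_names),
        "HM+SF": list(mark_names) + list(seq_names),
    }
    return {
        name: crossval(X, y, feats, model_params, n_repeats, n_folds, seed=seed)
        for name, feats in subsets.items()
    }


def rank_importance(
    X: pd.DataFrame,
    y: np.ndarray,
    feature_names: list[str],
    model_params: ModelParams | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean-decrease-Gini importance averaged over balanced sampling
    repeats; rank 1 is the most important, ties broken by the order features
    appear in `feature_names`."""
    model_params = model_params or ModelParams()
    y = np.asarray(y, dtype=int)
    Xs = X[list(feature_names)].to_numpy(dtype=float)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    master = np.random.default_rng(seed)
    repeat_seeds = master.integers(0, SEED_MOD, size=n_repeats)
    scores = np.zeros(len(feature_names))
    for rep_seed in repeat_seeds:
        rng = np.random.default_rng(int(rep_seed))
        idx = balanced_sample(pos_idx, neg_idx, rng)
        clf = model_params.build(int(rep_seed))
        clf.fit(Xs[idx], y[idx])
        scores += clf.feature_importances_
    scores /= n_repeats
    order = np.lexsort((np.arange(len(feature_names)), -scores))
    ranking = pd.DataFrame(
        {
            "feature": np.asarray(feature_names)[order],
            "mdg": scores[order],
            "rank": np.arange(1, len(feature_names) + 1),
        }
    )
    return ranking


def cumulative_curve(
    X: pd.DataFrame,
    y: np.ndarray,
    ranking: pd.DataFrame,
    model_params: ModelParams | None = None,
    n_repeats: int = 10,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """mean AUC of the nested top-n feature subsets, n = 1 .. n_features,
    all points computed on the same sampling repeats (shared seed)."""
    feats = list(ranking["feature"])
    rows = []
    for n in range(1, len(feats) + 1):
        res = crossval(X, y, feats[:n], model_params, n_repeats, n_folds, seed=seed)
        rows.append((n, ",".join(feats[:n]), res.mean_auc))
    return pd.DataFrame(rows, columns=["n", "features", "mean_auc"])


def essential_features(curve: pd.DataFrame, ranking: pd.DataFrame, k: int = 6) -> dict:
    """The top-k features by importance, with the cumulative curve's AUC at
    that size attached."""
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds the {len(ranking)} available features")
    feats = list(ranking["feature"].iloc[:k])
    auc_k = float(curve.loc[curve["n"] == k, "mean_auc"].iloc[0])
    return {"features": feats, "k": k, "mean_auc": auc_k}
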