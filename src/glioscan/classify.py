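"""Molecular-marker prediction workflow.

Correlation elimination with a univariate-AUC survivor rule, stratified
70/30 splitting, cumulative random-forest importance ranking over randomly
sampled hyperparameters (top-20 selection), randomized model search over
gradient-boosted trees / random forest / logistic regression, repeated-split
evaluation of the top candidates (guarding against the "lucky split"),
probability-averaging ensembles, bootstrap AUC confidence intervals, and
per-feature class-heterogeneity tests (Mann-Whitney with Bonferroni).

Every randomized operation derives its inner seeds deterministically from a
single master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from xgboost import XGBClassifier

log = logging.getLogger(__name__)


def rank_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC via the tie-corrected rank formulation (ties count 1/2)."""
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class HyperparameterRange:
    """Named uniform sampling intervals per learner family."""

    rf_n_estimators: tuple[int, int] = (20, 300)
    rf_max_depth: tuple[int, int] = (2, 6)
    xgb_n_estimators: tuple[int, int] = (20, 300)
    xgb_max_depth: tuple[int, int] = (2, 6)
    xgb_learning_rate: tuple[float, float] = (0.01, 0.3)   # log-uniform
    xgb_reg_lambda: tuple[float, float] = (1e-3, 10.0)     # log-uniform
    logreg_c: tuple[float, float] = (1e-3, 1e3)            # log-uniform

    def __post_init__(self) -> None:
        for name, (lo, hi) in vars(self).items():
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


@dataclass
class ClassifierSearchResult:
    family: str
    params: dict
    aucs: list[float] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))


def eliminate_correlated_by_auc(
    features: pd.DataFrame, labels: pd.Series, threshold: float = 0.85
) -> list[str]:
    """Greedy elimination of |Spearman rs| > threshold pairs, dropping the
    member with the lower univariate ROC AUC (folded to max(AUC, 1-AUC));
    AUC ties break lexicographically. Deterministic."""
    from .survival import eliminate_correlated

    y = labels.loc[features.index].to_numpy()
    scores = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if x.std() == 0:
            scores[col] = 0.0
            continue
        a = rank_auc(y, x)
        scores[col] = max(a, 1.0 - a)
    return eliminate_correlated(features, threshold=threshold, keep_scores=scores)


def stratified_split(
    X: pd.DataFrame, y: pd.Series, ratio: float = 0.7, seed: int = 0
):
    """Label-stratified random split; class proportions preserved within
    one patient."""
    counts = y.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("both classes need at least two members")
    idx_tr, idx_te = train_test_split(
        np.asarray(X.index), train_size=ratio, stratify=y.to_numpy(),
        random_state=int(seed) % 2**31,
    )
    return (X.loc[idx_tr], y.loc[idx_tr]), (X.loc[idx_te], y.loc[idx_te])


def rf_importance_rank(
    X: pd.DataFrame,
    y: pd.Series,
    n_iter: int = 1000,
    ranges: HyperparameterRange = HyperparameterRange(),
    seed: int = 0,
    top_k: int = 20,
) -> tuple[list[str], pd.Series]:
    """Cumulative impurity-based importance over `n_iter` random-forest fits
    with uniformly sampled hyperparameters; returns (top_k ranked ids,
    cumulative importance histogram). Constant columns rank last."""
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=int)
    cum = np.zeros(X.shape[1])
    for _ in range(n_iter):
        rf = RandomForestClassifier(
            n_estimators=int(rng.integers(ranges.rf_n_estimators[0],
                                          ranges.rf_n_estimators[1] + 1)),
            max_depth=int(rng.integers(ranges.rf_max_depth[0],
                                       ranges.rf_max_depth[1] + 1)),
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        rf.fit(Xv, yv)
        cum += rf.feature_importances_
    hist = pd.Series(cum, index=X.columns).sort_values(ascending=False)
    order = sorted(X.columns, key=lambda c: (-hist[c], c))
    k = min(top_k, len(order)) if X.shape[1] >= top_k else len(order)
    return order[:k], hist


def _make_candidate(family: str, rng: np.random.Generator,
                    ranges: HyperparameterRange) -> ClassifierSearchResult:
    if family == "xgboost":
        params = {
            "n_estimators": int(rng.integers(ranges.xgb_n_estimators[0],
                                             ranges.xgb_n_estimators[1] + 1)),
            "max_depth": int(rng.integers(ranges.xgb_max_depth[0],
                                          ranges.xgb_max_depth[1] + 1)),
            "learning_rate": _log_uniform(rng, *ranges.xgb_learning_rate),
            "reg_lambda": _log_uniform(rng, *ranges.xgb_reg_lambda),
        }
    elif family == "random_forest":
        params = {
            "n_estimators": int(rng.integers(ranges.rf_n_estimators[0],
                                             ranges.rf_n_estimators[1] + 1)),
            "max_depth": int(rng.integers(ranges.rf_max_depth[0],
                                          ranges.rf_max_depth[1] + 1)),
        }
    elif family == "logistic_regression":
        params = {"C": _log_uniform(rng, *ranges.logreg_c)}
    else:
        raise ValueError(f"unknown learner family: {family}")
    return ClassifierSearchResult(family=family, params=params)


def build_estimator(cand: ClassifierSearchResult, seed: int):
    if cand.family == "xgboost":
        return XGBClassifier(
            **cand.params, random_state=seed, n_jobs=1, eval_metric="logloss",
            verbosity=0,
        )
    if cand.family == "random_forest":
        return RandomForestClassifier(**cand.params, random_state=seed, n_jobs=1)
    return LogisticRegression(**cand.params, max_iter=2000, random_state=seed)


def fit_score(cand: ClassifierSearchResult, Xtr, ytr, Xte, yte, seed: int) -> float:
    est = build_estimator(cand, seed)
    est.fit(Xtr.to_numpy(dtype=float), ytr.to_numpy(dtype=int))
    probs = est.predict_proba(Xte.to_numpy(dtype=float))[:, 1]
    return rank_auc(yte.to_numpy(dtype=int), probs)


def model_search(
    Xtr: pd.DataFrame, ytr: pd.Series, Xte: pd.DataFrame, yte: pd.Series,
    families: tuple[str, ...] = ("xgboost", "random_forest", "logistic_regression"),
    n_iter: int = 1000,
    ranges: HyperparameterRange = HyperparameterRange(),
    seed: int = 0,
) -> list[ClassifierSearchResult]:
    """Randomized hyperparameter search: `n_iter` candidates with uniformly
    sampled hyperparameters (family round-robin), each trained on the train
    split and scored by test AUC; returned ranked by that score."""
    rng = np.random.default_rng(seed)
    results = []
    for i in range(n_iter):
        family = families[i % len(families)]
        cand = _make_candidate(family, rng, ranges)
        try:
            auc = fit_score(cand, Xtr, ytr, Xte, yte, seed=int(rng.integers(2**31)))
        except Exception as exc:  # non-convergent candidate: recorded, unranked
            log.warning("candidate %s %s failed: %s", family, cand.params, exc)
            continue
        cand.aucs.append(auc)
        results.append(cand)
    results.sort(key=lambda c: (-c.mean_auc, c.family, sorted(c.params.items())))
    return results


def repeated_split_eval(
    top_models: list[ClassifierSearchResult],
    X: pd.DataFrame,
    y: pd.Series,
    n_repeats: int = 10,
    ratio: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-split `n_repeats` times with fresh seeds, retrain and re-score each
    candidate; rows are candidates with mean and spread of the AUC. The
    winner is the best mean. Splits lacking a class are redrawn (logged)."""
    rng = np.random.default_rng(seed)
    rows = []
    split_seeds = []
    while len(split_seeds) < n_repeats:
        s = int(rng.integers(2**31))
        try:
            stratified_split(X, y, ratio=ratio, seed=s)
        except ValueError:
            log.warning("split seed %d lacks a class; redrawn", s)
            continue
        split_seeds.append(s)
    for rank, cand in enumerate(top_models):
        aucs = []
        for s in split_seeds:
            (Xtr, ytr), (Xte, yte) = stratified_split(X, y, ratio=ratio, seed=s)
            aucs.append(fit_score(cand, Xtr, ytr, Xte, yte, seed=s))
        rows.append({
            "rank_in_search": rank, "family": cand.family, "params": str(cand.params),
            "mean_auc": float(np.mean(aucs)), "sd_auc": float(np.std(aucs)),
            "aucs": aucs,
        })
    return pd.DataFrame(rows).sort_values("mean_auc", ascending=False).reset_index(drop=True)


def ensemble_average(probs_a: np.ndarray, probs_b: np.ndarray) -> np.ndarray:
    """Elementwise mean of two predicted-probability vectors over the same
    patients. Symmetric; idempotent on identical inputs."""
    a = np.asarray(probs_a, dtype=float)
    b = np.asarray(probs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if ((a < 0) | (a > 1) | (b < 0) | (b > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return (a + b) / 2.0


def bootstrap_auc_ci(
    y: pd.Series | np.ndarray,
    probs: np.ndarray,
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """AUC with a percentile 95% CI from patient-level resampling; resamples
    missing a class are redrawn (logged)."""
    y = np.asarray(y, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    if min(y.sum(), len(y) - y.sum()) < 1 or len(y) < 3:
        raise ValueError("too few patients to bootstrap")
    auc = rank_auc(y, probs)
    rng = np.random.default_rng(seed)
    boots = []
    redraws = 0
    while len(boots) < n_boot:
        idx = rng.integers(len(y), size=len(y))
        if y[idx].sum() in (0, len(y)):
            redraws += 1
            if redraws > 100 * n_boot:
                raise ValueError("resamples cannot contain both classes")
            continue
        boots.append(rank_auc(y[idx], probs[idx]))
    if redraws:
        log.info("redrew %d degenerate bootstrap resamples", redraws)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(auc), (float(lo), float(hi))


def heterogeneity_histograms(
    features: pd.DataFrame,
    labels: pd.Series,
    plot_dir=None,
) -> pd.DataFrame:
    """Per-feature Mann-Whitney test between outcome groups with Bonferroni
    correction (multiplied by the feature count, capped at 1); optional
    class-conditional histogram plots."""
    y = labels.loc[features.index].to_numpy(dtype=int)
    m = features.shape[1]
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        a, b = x[y == 1], x[y == 0]
        if np.all(x == x[0]):
            raw = 1.0
        else:
            raw = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"feature": col, "p_raw": raw, "p_bonferroni": min(raw * m, 1.0)})
    table = pd.DataFrame(rows).set_index("feature")
    if plot_dir is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from pathlib import Path

        d = Path(plot_dir)
        d.mkdir(parents=True, exist_ok=True)
        for col in features.columns:
            fig, ax = plt.subplots(figsize=(4, 3))
            for lab, name in [(0, "negative"), (1, "positive")]:
                ax.hist(features.loc[y == lab, col], bins=20, alpha=0.5, label=name,
                        density=True)
            ax.set_title(col, fontsize=8)
            ax.legend(fontsize=7)
            fig.tight_layout()
            fig.savefig(d / f"{col}.svg")
            plt.close(fig)
    return table
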