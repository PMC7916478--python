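"""Prognostic survival workflow: univariate screening, correlation
elimination, multivariable Cox fitting with backward elimination, prognostic
index (PI) construction and stacking, and the multi-step external-validation
diagnostics (Harrell's C, calibration slope, misspecification test,
percentile risk-group split with observed and model-predicted curves).

The PI of a model with coefficients beta over features x is sum_i beta_i x_i,
centered at the training feature means so stacked models share a comparable
baseline. Cox fits use Efron tie handling whenever tied event times are
present (without ties Efron and Breslow coincide and the cheaper Breslow
path is taken).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

log = logging.getLogger(__name__)

_MAX_ABS_BETA = 50.0  # beyond this the partial likelihood is monotone (separation)


class _quiet_fit:
    """Silence the expected numerical noise of exploratory Cox fits
    (separation and non-convergence are detected and handled explicitly)."""

    def __enter__(self):
        import warnings as _w
        self._w = _w.catch_warnings()
        self._w.__enter__()
        _w.simplefilter("ignore")
        self._e = np.errstate(all="ignore")
        self._e.__enter__()
        return self

    def __exit__(self, *exc):
        self._e.__exit__(*exc)
        return self._w.__exit__(*exc)


@dataclass
class CoxModel:
    """Fitted proportional-hazards model: named coefficients + provenance."""

    beta: dict[str, float]
    se: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    center: dict[str, float] = field(default_factory=dict)
    cohort_tag: str = ""

    @property
    def feature_ids(self) -> list[str]:
        return list(self.beta)

    @property
    def hazard_ratios(self) -> dict[str, float]:
        return {k: float(np.exp(b)) for k, b in self.beta.items()}

    @property
    def centering_constant(self) -> float:
        return float(sum(self.beta[k] * self.center.get(k, 0.0) for k in self.beta))

    @classmethod
    def from_hazard_ratios(cls, hrs: dict[str, float], cohort_tag: str = "published") -> "CoxModel":
        return cls(beta={k: float(np.log(v)) for k, v in hrs.items()}, cohort_tag=cohort_tag)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CoxModel":
        return cls(**json.loads(Path(path).read_text()))


def _check_surv(surv: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(surv["time"], dtype=float)
    event = np.asarray(surv["event"], dtype=int)
    if (time < 0).any():
        raise ValueError("negative survival times")
    return time, event


def _tie_method(time: np.ndarray, event: np.ndarray) -> str:
    """Efron and Breslow coincide without tied event times; Breslow is much
    cheaper, so use it when ties are absent."""
    ev_times = time[event == 1]
    return "efron" if len(np.unique(ev_times)) < len(ev_times) else "breslow"


def _fast_univariate_cox(x: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Newton-Raphson for a single-covariate Cox partial likelihood with no
    tied event times (risk sets are prefixes after sorting by descending
    time). Returns (beta, se, wald_p); None if it fails to converge."""
    order = np.argsort(-time, kind="stable")
    xs = x[order]
    ev = event[order].astype(bool)
    beta = 0.0
    h = -1.0
    for _ in range(30):
        w = np.exp(np.clip(beta * xs, -700, 700))
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * xs)
        s2 = np.cumsum(w * xs * xs)
        i = np.flatnonzero(ev)
        m1 = s1[i] / s0[i]
        g = float(np.sum(xs[i] - m1))
        h = float(-np.sum(s2[i] / s0[i] - m1 * m1))
        if h >= 0 or not np.isfinite(h):
            return None
        step = -g / h
        beta += np.clip(step, -5.0, 5.0)
        if abs(step) < 1e-10:
            break
    else:
        return None
    if not np.isfinite(beta) or abs(beta) > _MAX_ABS_BETA:
        return None
    se = float(np.sqrt(-1.0 / h))
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return beta, se, p


def fit_cox(features: pd.DataFrame, surv: pd.DataFrame, cohort_tag: str = "train") -> CoxModel:
    """Maximize the Cox partial likelihood (Efron ties). Zero-variance
    columns get an exact zero coefficient; separation raises with the
    offending feature's name."""
    time, event = _check_surv(surv)
    cols = list(features.columns)
    if event.sum() < len(cols):
        raise ValueError(
            f"{int(event.sum())} events for {len(cols)} features; reduce the feature set"
        )
    X = features.to_numpy(dtype=float)
    variable = X.std(axis=0) > 0
    beta = dict.fromkeys(cols, 0.0)
    se = dict.fromkeys(cols, float("inf"))
    pv = dict.fromkeys(cols, 1.0)
    if variable.any():
        sub = [c for c, v in zip(cols, variable) if v]
        try:
            with _quiet_fit():
                res = PHReg(time, X[:, variable], status=event,
                            ties=_tie_method(time, event)).fit(disp=False)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"monotone likelihood (separation) while fitting feature(s) {sub}: {exc}"
            ) from exc
        # non-finite or runaway coefficients, or a singular hessian (zero SE),
        # all signal a monotone partial likelihood
        bad = (
            ~np.isfinite(res.params)
            | (np.abs(res.params) > _MAX_ABS_BETA)
            | ~np.isfinite(res.bse)
            | (res.bse == 0)
        )
        if bad.any():
            raise ValueError(
                f"monotone likelihood (separation) for feature(s): "
                f"{[c for c, b in zip(sub, bad) if b]}"
            )
        for c, b, s, p in zip(sub, res.params, res.bse, res.pvalues):
            beta[c], se[c], pv[c] = float(b), float(s), float(p)
    center = {c: float(features[c].mean()) for c in cols}
    return CoxModel(beta=beta, se=se, pvalues=pv, center=center, cohort_tag=cohort_tag)


def univariate_cox_screen(
    features: pd.DataFrame,
    surv: pd.DataFrame,
    alpha: float = 0.2,
    return_pvalues: bool = False,
):
    """Single-covariate Cox fit per feature; keep Wald p <= alpha.
    Constant features carry no information and are never selected.

    With `return_pvalues=True` returns (selected, {feature: wald_p})."""
    time, event = _check_surv(surv)
    if event.sum() < 1:
        raise ValueError("no events")
    # with strictly distinct times a dedicated Newton solver is exact and
    # much faster than the general engine
    fast_ok = len(np.unique(time)) == len(time)
    selected = []
    pvals: dict[str, float] = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if x.std() == 0:
            continue
        p = None
        if fast_ok:
            fit = _fast_univariate_cox(x, time, event)
            if fit is None:
                log.warning("separation in univariate fit for %s; dropped", col)
                continue
            p = fit[2]
        else:
            try:
                with _quiet_fit():
                    res = PHReg(time, x[:, None], status=event,
                                ties=_tie_method(time, event)).fit(disp=False)
            except Exception as exc:  # non-convergence: drop with log entry
                log.warning("univariate fit failed for %s (%s); dropped", col, exc)
                continue
            if not np.isfinite(res.params[0]) or abs(res.params[0]) > _MAX_ABS_BETA:
                log.warning("separation in univariate fit for %s; dropped", col)
                continue
            p = float(res.pvalues[0])
        if p <= alpha:
            selected.append(col)
            pvals[col] = p
    return (selected, pvals) if return_pvalues else selected


def eliminate_correlated(
    features: pd.DataFrame,
    threshold: float = 0.85,
    keep_scores: dict[str, float] | None = None,
) -> list[str]:
    """Eliminate features until no pair's |Spearman rs| strictly exceeds
    `threshold` (a pair at exactly the threshold is kept).

    Survivor rule (deterministic): candidates are visited in decreasing
    `keep_scores` order (ties: lexicographic id; without scores, lexicographic
    order) and kept only if not over-correlated with any already-kept
    feature — so of any violating pair the higher-scoring member survives."""
    cols = list(features.columns)
    if len(cols) < 2:
        return cols
    rs = stats.spearmanr(features.to_numpy(dtype=float), axis=0).statistic
    if np.ndim(rs) == 0:  # spearmanr collapses the 2-column case to a scalar
        rs = np.array([[1.0, rs], [rs, 1.0]])
    rs = np.abs(rs)
    np.fill_diagonal(rs, 0.0)
    idx = {c: k for k, c in enumerate(cols)}
    if keep_scores:
        order = sorted(cols, key=lambda c: (-keep_scores.get(c, float("-inf")), c))
    else:
        order = sorted(cols)
    kept: list[str] = []
    kept_idx: list[int] = []
    for c in order:
        k = idx[c]
        if not kept_idx or np.all(rs[k, kept_idx] <= threshold):
            kept.append(c)
            kept_idx.append(k)
    return [c for c in cols if c in set(kept)]


def backward_eliminate(
    features: pd.DataFrame,
    surv: pd.DataFrame,
    alpha: float = 0.2,
    cohort_tag: str = "train",
) -> CoxModel:
    """Iteratively refit, removing the feature with the largest Wald p while
    it exceeds `alpha` (ties: lexicographically larger id removed first).
    If a refit fails (separation/non-convergence) the last-ranked candidate
    is removed instead. May remove everything, in which case the PI is
    identically zero."""
    cols = list(features.columns)
    while cols:
        try:
            model = fit_cox(features[cols], surv, cohort_tag=cohort_tag)
        except ValueError as exc:
            log.warning("refit failed (%s); dropping %s", exc, cols[-1])
            cols.pop()
            continue
        worst = max(cols, key=lambda c: (model.pvalues[c], c))
        if model.pvalues[worst] > alpha:
            cols.remove(worst)
        else:
            return model
    log.warning("backward elimination removed every feature; PI is identically 0")
    return CoxModel(beta={}, cohort_tag=cohort_tag)


def compute_pi(model: CoxModel, features: pd.DataFrame) -> pd.Series:
    """Per-patient prognostic index sum_i beta_i (x_i - center_i). Patients
    missing any model feature are excluded with a log entry."""
    if not model.beta:
        return pd.Series(0.0, index=features.index, name="pi")
    missing_cols = [c for c in model.feature_ids if c not in features.columns]
    if missing_cols:
        raise KeyError(f"features table lacks model columns: {missing_cols}")
    sub = features[model.feature_ids]
    complete = sub.notna().all(axis=1)
    if (~complete).any():
        log.info("excluding %d patients with incomplete features", int((~complete).sum()))
    X = sub[complete].to_numpy(dtype=float)
    b = np.array([model.beta[c] for c in model.feature_ids])
    c0 = np.array([model.center.get(c, 0.0) for c in model.feature_ids])
    return pd.Series((X - c0) @ b, index=sub.index[complete], name="pi")


def stack_pi(component_pis: dict[str, pd.Series], surv: pd.DataFrame,
             cohort_tag: str = "train") -> CoxModel:
    """Cox fit with the component PIs as the only covariates (prognostic
    score stacking). Perfectly collinear components are rejected."""
    if len(component_pis) < 2:
        raise ValueError("stacking needs at least two component PIs")
    df = pd.DataFrame(component_pis).dropna()
    corr = df.corr().to_numpy()
    iu = np.triu_indices(len(component_pis), k=1)
    if np.any(np.isclose(np.abs(corr[iu]), 1.0)):
        raise ValueError("component PIs are perfectly collinear")
    return fit_cox(df, surv.loc[df.index], cohort_tag=cohort_tag)


CLINICAL_COVARIATES = [
    "sex_male", "surgery_resection", "age_over70", "adjuvant_non_stupp", "mgmt_methylated",
]


def clinical_model(clinical: pd.DataFrame, surv: pd.DataFrame,
                   cohort_tag: str = "train") -> CoxModel:
    """Full clinical Cox model: all declared covariates entered, no
    elimination."""
    missing = [c for c in CLINICAL_COVARIATES if c not in clinical.columns]
    if missing:
        raise KeyError(f"clinical table lacks required columns: {missing}")
    sub = clinical[CLINICAL_COVARIATES].dropna()
    return fit_cox(sub, surv.loc[sub.index], cohort_tag=cohort_tag)


def harrell_c(
    pi: pd.Series, surv: pd.DataFrame, n_boot: int = 500, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Censoring-aware concordance of the PI (ties count 1/2) with a
    percentile bootstrap 95% CI over patients."""
    df = pd.DataFrame({"pi": pi}).join(surv).dropna()
    time, event, p = df["time"].to_numpy(), df["event"].to_numpy(), df["pi"].to_numpy()
    if event.sum() == 0:
        raise ValueError("no comparable pairs (no events)")
    c = float(concordance_index(time, -p, event))
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(len(df), size=len(df))
        if event[idx].sum() == 0:
            continue
        try:
            boots.append(concordance_index(time[idx], -p[idx], event[idx]))
        except ZeroDivisionError:  # resample without admissible pairs
            continue
    lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
    return c, (float(lo), float(hi))


def calibration_slope(pi_val: pd.Series, surv_val: pd.DataFrame) -> tuple[float, float]:
    """Refit the frozen PI as the sole covariate on validation data.

    Returns (slope, p) where p is the likelihood-ratio test of slope = 1
    (via the offset comparison). Slope < 1 indicates training optimism."""
    df = pd.DataFrame({"pi": pi_val}).join(surv_val).dropna()
    time, event = _check_surv(df)
    if df["pi"].std() == 0:
        raise ValueError("PI is constant on validation; slope undefined")
    mod = PHReg(time, df[["pi"]].to_numpy(), status=event,
                ties=_tie_method(time, event))
    with _quiet_fit():
        res = mod.fit(disp=False)
    slope = float(res.params[0])
    lr = 2.0 * (mod.loglike(res.params) - mod.loglike(np.array([1.0])))
    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return slope, p


def misspecification_test(
    features_val: pd.DataFrame, model: CoxModel, surv_val: pd.DataFrame
) -> float:
    """Joint likelihood-ratio test that the individual signature features add
    nothing beyond the frozen PI (entered as an offset) on validation."""
    if not model.beta:
        raise ValueError("misspecification test undefined for an empty model")
    pi = compute_pi(model, features_val)
    df = features_val.loc[pi.index, model.feature_ids].join(surv_val).dropna()
    time, event = _check_surv(df)
    X = df[model.feature_ids].to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    off = pi.loc[df.index].to_numpy()
    mod = PHReg(time, X, status=event, offset=off,
                ties=_tie_method(time, event))
    try:
        with _quiet_fit():
            res = mod.fit(disp=False)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"misspecification fit degenerate on n={len(df)} validation "
            f"patients (singular information)"
        ) from exc
    lr = 2.0 * (mod.loglike(res.params) - mod.loglike(np.zeros(X.shape[1])))
    return float(stats.chi2.sf(max(lr, 0.0), df=X.shape[1]))


def breslow_baseline(pi: pd.Series, surv: pd.DataFrame):
    """Breslow estimate of the cumulative baseline hazard H0(t) given the
    linear predictor. Returns (event_times, H0) step-function knots."""
    df = pd.DataFrame({"pi": pi}).join(surv).dropna().sort_values("time")
    time, event, p = df["time"].to_numpy(), df["event"].to_numpy(), df["pi"].to_numpy()
    risk = np.exp(p)
    uniq = np.unique(time[event == 1])
    h0 = []
    for t in uniq:
        d = int(((time == t) & (event == 1)).sum())
        denom = risk[time >= t].sum()
        h0.append(d / denom)
    return uniq, np.cumsum(h0)


@dataclass
class KMSplitResult:
    threshold: float
    logrank_p: dict[str, float]
    groups: dict[str, pd.Series]          # cohort -> bool Series (True = high risk)
    observed: dict[str, dict[str, pd.DataFrame]]   # cohort -> group -> KM table
    predicted: dict[str, dict[str, pd.DataFrame]]  # cohort -> group -> mean predicted S(t)


def km_split(
    pi_train: pd.Series,
    surv_train: pd.DataFrame,
    pi_val: pd.Series | None = None,
    surv_val: pd.DataFrame | None = None,
    percentile: float = 75.0,
) -> KMSplitResult:
    """Split at the given percentile of the *training* PI (threshold frozen,
    then applied unchanged to validation). Produces observed KM curves,
    group-averaged model-predicted curves, and log-rank p per cohort."""
    threshold = float(np.percentile(pi_train.dropna(), percentile))
    t0, h0 = breslow_baseline(pi_train, surv_train)
    cohorts = {"train": (pi_train, surv_train)}
    if pi_val is not None and surv_val is not None:
        cohorts["val"] = (pi_val, surv_val)
    logrank_p, groups, observed, predicted = {}, {}, {}, {}
    for tag, (pi, surv) in cohorts.items():
        df = pd.DataFrame({"pi": pi}).join(surv).dropna()
        high = df["pi"] > threshold
        groups[tag] = high
        observed[tag], predicted[tag] = {}, {}
        if high.sum() == 0 or (~high).sum() == 0:
            log.warning("one risk group is empty in cohort %s; no log-rank test", tag)
            logrank_p[tag] = float("nan")
        else:
            res = logrank_test(
                df.loc[high, "time"], df.loc[~high, "time"],
                df.loc[high, "event"], df.loc[~high, "event"],
            )
            logrank_p[tag] = float(res.p_value)
        for gname, sel in [("high", high), ("low", ~high)]:
            if sel.sum() == 0:
                continue
            kmf = KaplanMeierFitter()
            kmf.fit(df.loc[sel, "time"], df.loc[sel, "event"])
            observed[tag][gname] = kmf.survival_function_.rename(
                columns={"KM_estimate": "S"}
            )
            # predicted curve: S_i(t) = exp(-H0(t) e^{pi_i}), averaged over the group
            s_pred = np.exp(-np.outer(h0, np.exp(df.loc[sel, "pi"]))).mean(axis=1)
            predicted[tag][gname] = pd.DataFrame({"S": s_pred}, index=pd.Index(t0, name="time"))
    return KMSplitResult(threshold, logrank_p, groups, observed, predicted)


def volume_correlation_check(features: pd.DataFrame, volume: pd.Series) -> pd.DataFrame:
    """Spearman rs of each feature against tumor volume (mm^3)."""
    rows = []
    v = volume.loc[features.index]
    for col in features.columns:
        r, p = stats.spearmanr(features[col], v)
        rows.append({"feature": col, "spearman_rs": float(r), "p": float(p)})
    return pd.DataFrame(rows).set_index("feature")


def _is_binary(s: pd.Series) -> bool:
    vals = s.dropna().unique()
    return len(vals) <= 2


def cross_block_correlation(blocks: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise correlation across feature blocks (VASARI / radiomics /
    clinical): point-biserial for binary-vs-continuous, Spearman for
    continuous pairs, phi (Pearson) for binary pairs. Zero-variance columns
    are skipped with a note."""
    rows = []
    names = list(blocks)
    for ai in range(len(names)):
        for bi in range(ai + 1, len(names)):
            A, B = blocks[names[ai]], blocks[names[bi]]
            common = A.index.intersection(B.index)
            for ca in A.columns:
                for cb in B.columns:
                    x = pd.to_numeric(A.loc[common, ca], errors="coerce")
                    y = pd.to_numeric(B.loc[common, cb], errors="coerce")
                    ok = x.notna() & y.notna()
                    x, y = x[ok], y[ok]
                    if len(x) < 3 or x.std() == 0 or y.std() == 0:
                        log.info("skipping %s vs %s (degenerate)", ca, cb)
                        continue
                    bx, by = _is_binary(x), _is_binary(y)
                    if bx and by:
                        r, p = stats.pearsonr(x, y)
                        method = "phi"
                    elif bx or by:
                        b, c = (x, y) if bx else (y, x)
                        r, p = stats.pointbiserialr(b.astype(int), c)
                        method = "point_biserial"
                    else:
                        r, p = stats.spearmanr(x, y)
                        method = "spearman"
                    rows.append({
                        "block_a": names[ai], "feature_a": ca,
                        "block_b": names[bi], "feature_b": cb,
                        "method": method, "r": float(r), "p": float(p),
                    })
    return pd.DataFrame(rows)
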