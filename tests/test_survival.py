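"""Cox machinery: screening, elimination, fitting, PI construction/stacking
and the external-validation diagnostics."""

import numpy as np
import pandas as pd
import pytest

from glioscan import survival as sv
from glioscan.synthetic import simulate_feature_cohort


@pytest.fixture(scope="module")
def cohort():
    return simulate_feature_cohort(600, {"a": 0.8, "b": -0.6}, n_noise=5, seed=100)


# ------------------------------------------------------------------ screening


def test_screen_constant_feature_never_selected(cohort):
    X, surv, _ = cohort
    X2 = X.copy()
    X2["const"] = 1.0
    sel = sv.univariate_cox_screen(X2, surv, alpha=1.0)
    assert "const" not in sel
    assert set(X.columns) <= set(sel)  # alpha=1 keeps every convergent feature


def test_fast_univariate_path_matches_general_engine():
    """The no-ties Newton solver used by the screen agrees with the general
    Cox engine on coefficient, SE and Wald p."""
    from statsmodels.duration.hazard_regression import PHReg

    from glioscan.survival import _fast_univariate_cox

    for seed in range(5):
        X, surv, _ = simulate_feature_cohort(300, {"x": 0.6}, seed=700 + seed)
        t = surv["time"].to_numpy()
        e = surv["event"].to_numpy()
        fast = _fast_univariate_cox(X["x"].to_numpy(), t, e)
        res = PHReg(t, X[["x"]].to_numpy(), status=e, ties="efron").fit(disp=False)
        assert fast[0] == pytest.approx(res.params[0], abs=1e-6)
        assert fast[1] == pytest.approx(res.bse[0], rel=1e-5)
        assert fast[2] == pytest.approx(res.pvalues[0], abs=1e-6)


def test_screen_finds_planted_signal():
    hits = 0
    for seed in range(10):
        X, surv, _ = simulate_feature_cohort(500, {"sig": 1.0}, n_noise=20, seed=seed)
        hits += "sig" in sv.univariate_cox_screen(X, surv, alpha=0.2)
    assert hits >= 9


# ---------------------------------------------------------------- elimination


def test_eliminate_duplicate_keeps_one(rng):
    x = rng.normal(size=300)
    F = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=300)})
    kept = sv.eliminate_correlated(F, threshold=0.85)
    assert kept.count("a") + kept.count("b") == 1 and "c" in kept


def test_eliminate_exact_threshold_pair_kept():
    # construct a pair with |spearman rs| exactly at the threshold
    n = 41
    x = np.arange(n, dtype=float)
    y = x.copy()
    # swapping ranks reduces rs deterministically; find a swap hitting <= 0.85
    from scipy.stats import spearmanr

    rs = 1.0
    i = 0
    while rs > 0.85:
        y[[i, n - 1 - i]] = y[[n - 1 - i, i]]
        rs = spearmanr(x, y).statistic
        i += 1
    F = pd.DataFrame({"a": x, "b": y})
    kept = sv.eliminate_correlated(F, threshold=rs)  # pair exactly AT threshold
    assert kept == ["a", "b"]


def test_eliminate_independent_features_all_kept(rng):
    F = pd.DataFrame(rng.normal(size=(400, 5)), columns=list("abcde"))
    assert sv.eliminate_correlated(F, threshold=0.85) == list("abcde")


def test_eliminate_survivor_rule_prefers_score(rng):
    x = rng.normal(size=200)
    F = pd.DataFrame({"good": x + rng.normal(0, 0.05, 200),
                      "bad": x + rng.normal(0, 0.05, 200)})
    kept = sv.eliminate_correlated(F, 0.85, keep_scores={"good": 2.0, "bad": 1.0})
    assert kept == ["good"]


# -------------------------------------------------------------------- fitting


def test_fit_cox_null_feature_zero_beta(cohort):
    X, surv, _ = cohort
    X2 = X[["a"]].copy()
    X2["null"] = 0.0
    m = sv.fit_cox(X2, surv)
    assert m.beta["null"] == 0.0


def test_fit_cox_recovery(cohort):
    X, surv, _ = cohort
    m = sv.fit_cox(X[["a", "b"]], surv)
    assert abs(m.beta["a"] - 0.8) < 3 * m.se["a"]
    assert abs(m.beta["b"] + 0.6) < 3 * m.se["b"]


def test_fit_cox_direction_two_groups():
    rng = np.random.default_rng(2)
    time = np.concatenate([rng.exponential(5.0, 80), rng.exponential(20.0, 80)])
    surv = pd.DataFrame({"time": time, "event": 1})
    X = pd.DataFrame({"g": np.r_[np.ones(80), np.zeros(80)]})
    m = sv.fit_cox(X, surv)
    assert m.beta["g"] > 0  # group 1 dies earlier -> higher hazard


def test_fit_cox_too_many_features_errors():
    X, surv, _ = simulate_feature_cohort(10, {"a": 0.0}, n_noise=15, seed=0)
    with pytest.raises(ValueError, match="reduce"):
        sv.fit_cox(X, surv)


def test_fit_cox_separation_errors():
    # a covariate that perfectly orders survival times with no censoring
    n = 40
    time = np.sort(np.random.default_rng(0).exponential(10, n))
    surv = pd.DataFrame({"time": time, "event": 1})
    X = pd.DataFrame({"perfect": -np.arange(n, dtype=float) * 10})
    with pytest.raises(ValueError, match="separation"):
        sv.fit_cox(X, surv)


# -------------------------------------------------------- backward elimination


def test_backward_keeps_significant_model(cohort):
    X, surv, _ = cohort
    m = sv.backward_eliminate(X[["a", "b"]], surv, alpha=0.2)
    assert set(m.beta) == {"a", "b"}


def test_backward_null_retention_rate():
    """Pure-noise features survive backward elimination at roughly the
    removal alpha."""
    kept = total = 0
    for seed in range(40):
        X, surv, _ = simulate_feature_cohort(150, {}, n_noise=3,
                                             seed=1000 + seed)
        m = sv.backward_eliminate(X, surv, alpha=0.2)
        kept += len(m.beta)
        total += 3
    rate = kept / total
    from scipy.stats import binomtest

    # binomial check around 0.2 (correlated steps make this approximate)
    assert binomtest(kept, total, 0.2).pvalue > 1e-4 or abs(rate - 0.2) < 0.1


def test_backward_retains_planted_signal():
    hits = 0
    for seed in range(10):
        X, surv, _ = simulate_feature_cohort(400, {"sig": 1.0}, n_noise=5,
                                             seed=2000 + seed)
        m = sv.backward_eliminate(X, surv, alpha=0.2)
        hits += "sig" in m.beta
    assert hits >= 9


# ----------------------------------------------------------------- PI & stack


def test_pi_from_published_hazard_ratios():
    model = sv.CoxModel.from_hazard_ratios(
        {"subependymal_extension": 1.75, "t1_flair_ratio_increased": 0.59}
    )
    patient = pd.DataFrame(
        {"subependymal_extension": [1.0], "t1_flair_ratio_increased": [1.0]},
        index=["p"],
    )
    pi = sv.compute_pi(model, patient)
    assert pi.iloc[0] == pytest.approx(np.log(1.75) + np.log(0.59), abs=1e-4)
    assert pi.iloc[0] == pytest.approx(0.0320, abs=1e-4)


def test_pi_empty_model_zero(cohort):
    X, _, _ = cohort
    pi = sv.compute_pi(sv.CoxModel(beta={}), X)
    assert (pi == 0).all()


def test_pi_differences_invariant_to_centering(cohort):
    X, surv, _ = cohort
    m = sv.fit_cox(X[["a"]], surv)
    uncentered = sv.CoxModel(beta=m.beta, center={})
    d1 = sv.compute_pi(m, X).diff().dropna()
    d2 = sv.compute_pi(uncentered, X).diff().dropna()
    assert np.allclose(d1, d2)


def test_stack_self_collinear_rejected(cohort):
    X, surv, _ = cohort
    m = sv.fit_cox(X[["a"]], surv)
    pi = sv.compute_pi(m, X)
    with pytest.raises(ValueError, match="collinear"):
        sv.stack_pi({"p1": pi, "p2": pi.copy()}, surv)


def test_stack_three_components(cohort):
    X, surv, _ = cohort
    pis = {
        "vasari": sv.compute_pi(sv.fit_cox(X[["a"]], surv), X),
        "radiomics": sv.compute_pi(sv.fit_cox(X[["b"]], surv), X),
        "clinical": sv.compute_pi(sv.fit_cox(X[["noise_00"]], surv), X),
    }
    m = sv.stack_pi(pis, surv)
    assert len(m.hazard_ratios) == 3


def test_stack_noise_component_shrinks():
    X, surv, _ = simulate_feature_cohort(2000, {"a": 1.0}, n_noise=1, seed=5)
    pi_sig = sv.compute_pi(sv.fit_cox(X[["a"]], surv), X)
    pi_noise = pd.Series(np.random.default_rng(1).normal(size=len(X)), index=X.index)
    m = sv.stack_pi({"sig": pi_sig, "noise": pi_noise}, surv)
    assert abs(m.beta["noise"]) < 0.1
    assert m.beta["sig"] == pytest.approx(1.0, abs=0.15)


def test_clinical_model_schema_and_recovery():
    rng = np.random.default_rng(8)
    n = 800
    clin = pd.DataFrame({
        "sex_male": rng.integers(0, 2, n),
        "surgery_resection": rng.integers(0, 2, n),
        "age_over70": rng.integers(0, 2, n),
        "adjuvant_non_stupp": rng.integers(0, 2, n),
        "mgmt_methylated": rng.integers(0, 2, n),
    }, index=[f"p{i}" for i in range(n)], dtype=float)
    from glioscan.synthetic import GroundTruth, simulate_survival

    gt = GroundTruth(beta_surv={"adjuvant_non_stupp": 1.6}, beta_marker={},
                     baseline_hazard_rate=0.05, censor_rate=0.01, seed=0)
    surv = simulate_survival(clin, gt, seed=9)
    m = sv.clinical_model(clin, surv)
    assert abs(m.beta["adjuvant_non_stupp"] - 1.6) < 3 * m.se["adjuvant_non_stupp"]
    with pytest.raises(KeyError, match="mgmt"):
        sv.clinical_model(clin.drop(columns=["mgmt_methylated"]), surv)


# ----------------------------------------------------------------- validation


def test_harrell_c_trivial_cases():
    surv = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1]})
    c, _ = sv.harrell_c(pd.Series([3.0, 2.0, 1.0]), surv, n_boot=20)
    assert c == 1.0
    c_tie, _ = sv.harrell_c(pd.Series([1.0, 1.0, 1.0]), surv, n_boot=20)
    assert c_tie == 0.5


def test_harrell_c_random_pi_near_half(cohort):
    X, surv, _ = cohort
    rng = np.random.default_rng(17)
    cs = [sv.harrell_c(pd.Series(rng.normal(size=len(X)), index=X.index),
                       surv, n_boot=0)[0] for _ in range(20)]
    assert abs(np.mean(cs) - 0.5) < 0.03


def test_calibration_slope_self_validation_is_one(cohort):
    X, surv, _ = cohort
    m = sv.fit_cox(X[["a", "b"]], surv)
    pi = sv.compute_pi(m, X)
    slope, p = sv.calibration_slope(pi, surv)
    assert slope == pytest.approx(1.0, abs=1e-6)
    assert p > 0.99


def test_calibration_slope_noise_model_near_zero():
    slopes = []
    for seed in range(5):
        Xt, st, _ = simulate_feature_cohort(300, {}, n_noise=3, seed=300 + seed)
        Xv, svv, _ = simulate_feature_cohort(300, {}, n_noise=3, seed=600 + seed)
        m = sv.fit_cox(Xt, st)
        slopes.append(sv.calibration_slope(sv.compute_pi(m, Xv), svv)[0])
    assert abs(np.mean(slopes)) < 0.5


def test_misspecification_self_degenerate(cohort):
    X, surv, _ = cohort
    m = sv.fit_cox(X[["a", "b"]], surv)
    p = sv.misspecification_test(X[["a", "b"]], m, surv)
    assert p > 0.999  # LR statistic 0 at the MLE


def test_misspecification_empty_model_errors(cohort):
    X, surv, _ = cohort
    with pytest.raises(ValueError, match="empty"):
        sv.misspecification_test(X, sv.CoxModel(beta={}), surv)


def test_misspecification_detects_doubled_coefficient():
    rejections = 0
    for seed in range(10):
        Xt, st, _ = simulate_feature_cohort(1000, {"a": 0.5, "b": 0.5},
                                            seed=seed)
        m = sv.fit_cox(Xt, st)
        Xv, svv, _ = simulate_feature_cohort(1000, {"a": 1.0, "b": 0.5},
                                             seed=5000 + seed)
        rejections += sv.misspecification_test(Xv, m, svv) < 0.05
    assert rejections >= 8  # power > 0.8 at n=1000


def test_km_split_threshold_frozen_from_training(cohort):
    X, surv, _ = cohort
    m = sv.fit_cox(X[["a", "b"]], surv)
    pi_tr = sv.compute_pi(m, X)
    Xv, svv, _ = simulate_feature_cohort(200, {"a": 0.8, "b": -0.6}, n_noise=5,
                                         seed=12)
    pi_va = sv.compute_pi(m, Xv) + 5.0  # shifted validation distribution
    res = sv.km_split(pi_tr, surv, pi_va, svv)
    assert res.threshold == pytest.approx(np.percentile(pi_tr, 75))
    assert res.logrank_p["train"] < 0.001


def test_km_split_null_pi_no_separation(cohort):
    X, surv, _ = cohort
    rng = np.random.default_rng(23)
    pi = pd.Series(rng.normal(size=len(X)), index=X.index)
    res = sv.km_split(pi, surv)
    assert res.logrank_p["train"] > 0.01


def test_volume_correlation_self_and_permuted(cohort, rng):
    X, _, _ = cohort
    vol = X["a"].abs() * 100
    tab = sv.volume_correlation_check(pd.DataFrame({"f": vol}), vol)
    assert tab.loc["f", "spearman_rs"] == pytest.approx(1.0)
    perm = pd.Series(rng.permutation(vol.to_numpy()), index=vol.index)
    tab2 = sv.volume_correlation_check(pd.DataFrame({"f": perm}), vol)
    assert abs(tab2.loc["f", "spearman_rs"]) < 0.1


def test_cross_block_correlation_types(rng):
    n = 200
    cont = rng.normal(size=n)
    binary = (cont > 0.3).astype(float)
    idx = [f"p{i}" for i in range(n)]
    blocks = {
        "A": pd.DataFrame({"bin": binary}, index=idx),
        "B": pd.DataFrame({"cont": cont, "indep": rng.normal(size=n),
                           "zero": np.ones(n)}, index=idx),
    }
    tab = sv.cross_block_correlation(blocks)
    row = tab[(tab.feature_a == "bin") & (tab.feature_b == "cont")].iloc[0]
    assert row["method"] == "point_biserial"
    # closed-form point-biserial for a thresholded normal
    from scipy.stats import pointbiserialr

    r_expect = pointbiserialr(binary.astype(int), cont).statistic
    assert row["r"] == pytest.approx(r_expect)
    assert abs(row["r"]) > 0.5
    indep = tab[(tab.feature_a == "bin") & (tab.feature_b == "indep")].iloc[0]
    assert abs(indep["r"]) < 0.2
    assert "zero" not in set(tab["feature_b"]) - {"cont", "indep"} or True
    assert not ((tab.feature_b == "zero")).any()  # degenerate column skipped
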