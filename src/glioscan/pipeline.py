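"""End-to-end study orchestration: simulate -> preprocess -> extract ->
model (prognostic / predictive) -> validate -> report.

A single master seed determines every stochastic sub-seed; two runs with the
same config produce bit-identical CSV/JSON artifacts. The expensive stages
(simulate tables, feature extraction) are cached on disk keyed by a content
hash of their config section, so partial runs resume from cached outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import survival as surv
from . import vasari
from .image import ImageVolume
from .preprocess import (
    PreprocessConfig,
    estimate_zscore_params,
    preprocess_pipeline,
    resample_mask,
    spacing_mode,
)
from .radiomics import FilterBankConfig, extract_features
from .synthetic import (
    GroundTruth,
    ScannerProfile,
    default_ground_truth,
    generate_cohorts,
    cohort_tables,
)

log = logging.getLogger(__name__)

__version__ = "0.1.0"

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "runs/demo",
    "simulate": {
        "n_train": 24,
        "n_val": 12,
        "fov_mm": [72.0, 72.0, 48.0],
        "missing_marker_fraction": 0.05,
        "profiles_train": [
            {"pixel_spacing_mm": [2.0, 2.0], "slice_thickness_mm": 4.0,
             "bias_amplitude": 0.2, "noise_sd": 4.0},
            {"pixel_spacing_mm": [1.5, 1.5], "slice_thickness_mm": 5.0,
             "bias_amplitude": 0.3, "noise_sd": 6.0},
        ],
        "profiles_val": [
            {"pixel_spacing_mm": [2.5, 2.5], "slice_thickness_mm": 5.0,
             "bias_amplitude": 0.35, "noise_sd": 6.0},
            {"pixel_spacing_mm": [2.0, 2.0], "slice_thickness_mm": 6.0,
             "bias_amplitude": 0.15, "noise_sd": 4.0},
        ],
        "write_images": False,
    },
    "preprocess": {
        "target_spacing": "mode",   # "mode" | [dx, dy, dz]
        "bias_correct": True,
        "equalize": True,
        "n4_shrink": 2,
        "n4_iterations": [20, 20],
    },
    "extract": {
        "log_sigmas_mm": [2.0, 3.0, 4.0, 5.0],
        "wavelet": True,
        "n_bins": 32,
        "include_shape": True,
        "shape_in_model_pool": False,
    },
    "prognostic": {
        "screen_alpha": 0.2,
        "removal_alpha": 0.2,
        "correlation_threshold": 0.85,
        "km_percentile": 75.0,
        "c_index_bootstrap": 200,
        "max_radiomics_candidates": 40,
    },
    "predictive": {
        "markers": ["MGMT"],
        "correlation_threshold": 0.85,
        "split_ratio": 0.7,
        "n_iter_importance": 60,
        "n_iter_search": 60,
        "n_repeats": 10,
        "top_k_models": 5,
        "n_bootstrap": 100,
        "vasari_family_overrides": {"MGMT": "logistic_regression"},
    },
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        _merge(cfg, user)
    if overrides:
        _merge(cfg, overrides)
    return cfg


def _merge(base: dict, upd: dict) -> None:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v


def _section_key(*sections) -> str:
    return hashlib.sha256(
        json.dumps(sections, sort_keys=True).encode()
    ).hexdigest()[:16]


def _profiles(spec_list) -> list[ScannerProfile]:
    return [
        ScannerProfile(
            pixel_spacing_mm=tuple(p["pixel_spacing_mm"]),
            slice_thickness_mm=p["slice_thickness_mm"],
            bias_amplitude=p.get("bias_amplitude", 0.0),
            noise_sd=p.get("noise_sd", 0.0),
        )
        for p in spec_list
    ]


def _write_json(path: Path, obj) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StudyRun:
    """Executes the configured stages and records a reproducibility manifest."""

    def __init__(self, config: dict):
        self.config = config
        self.out = Path(config["out_dir"])
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = int(config["seed"])
        self.manifest: dict = {
            "version": __version__,
            "master_seed": self.seed,
            "config": config,
            "stages": [],
            "artifacts": {},
        }
        self._cohorts = None  # in-memory patients (regenerated as needed)

    # ----------------------------------------------------------------- stages
    def simulate(self) -> None:
        cfg = self.config["simulate"]
        gt = default_ground_truth(seed=self.seed)
        train, val = generate_cohorts(
            cfg["n_train"], cfg["n_val"],
            _profiles(cfg["profiles_train"]), _profiles(cfg["profiles_val"]),
            gt,
            fov_mm=tuple(cfg["fov_mm"]),
            missing_marker_fraction=cfg["missing_marker_fraction"],
            out_dir=self.out / "data" if cfg.get("write_images") else None,
        )
        self._cohorts = (train, val, gt)
        d = self.out / "data"
        for tag, patients in [("train", train), ("val", val)]:
            (d / tag).mkdir(parents=True, exist_ok=True)
            for name, df in cohort_tables(patients).items():
                df.to_csv(d / tag / f"{name}.csv")
        _write_json(d / "ground_truth.json", asdict(gt))
        self._record("simulate", list(d.rglob("*.csv")) + [d / "ground_truth.json"])

    def _ensure_cohorts(self):
        if self._cohorts is None:
            self.simulate()
        return self._cohorts

    def extract(self) -> None:
        key = _section_key(self.seed, self.config["simulate"],
                           self.config["preprocess"], self.config["extract"])
        f_tr = self.out / "features_train.csv"
        f_va = self.out / "features_val.csv"
        vol_f = self.out / "volumes.csv"
        key_f = self.out / "extract.key"
        if f_tr.exists() and f_va.exists() and vol_f.exists() and key_f.exists() \
                and key_f.read_text() == key:
            log.info("extract stage: cache hit, resuming from %s", f_tr)
            self._record("extract", [f_tr, f_va, vol_f], cached=True)
            return
        train, val, _ = self._ensure_cohorts()
        pcfg = self.config["preprocess"]
        ecfg = self.config["extract"]
        target = pcfg["target_spacing"]
        if target == "mode":
            target = spacing_mode([p.t1.spacing_mm for p in train])
        target = tuple(target)
        fb = FilterBankConfig(
            log_sigmas_mm=tuple(ecfg["log_sigmas_mm"]),
            wavelet=ecfg["wavelet"],
            n_bins=ecfg["n_bins"],
            include_shape=ecfg["include_shape"],
        )
        pre = PreprocessConfig(
            target_spacing=target,
            bias_correct=pcfg["bias_correct"],
            equalize=pcfg["equalize"],
            zscore=False,  # params applied after training-cohort estimation
            n4_shrink=pcfg["n4_shrink"],
            n4_iterations=tuple(pcfg["n4_iterations"]),
        )

        def _stage_one(p):
            out = {}
            for mod, img, mask in [("t1", p.t1, p.t1_mask), ("t2", p.t2, p.t2_mask)]:
                proc, _ = preprocess_pipeline(img, None, pre)
                rmask = resample_mask(mask, img.spacing_mm, target)
                out[mod] = (proc, rmask)
            return out

        staged = {"train": [(p, _stage_one(p)) for p in train]}
        zparams = {
            mod: estimate_zscore_params([s[mod][0] for _, s in staged["train"]])
            for mod in ("t1", "t2")
        }
        staged["val"] = [(p, _stage_one(p)) for p in val]
        _write_json(self.out / "zscore_params.json",
                    {m: {"mu": z.mu, "sigma": z.sigma} for m, z in zparams.items()})

        volumes = {}
        manifest_written = False
        for tag, items in staged.items():
            rows = {}
            for p, s in items:
                vols = {}
                for mod in ("t1", "t2"):
                    proc, rmask = s[mod]
                    z = zparams[mod]
                    vols[mod] = (proc.with_values((proc.values - z.mu) / z.sigma), rmask)
                t1v, m1 = vols["t1"]
                t2v, m2 = vols["t2"]
                fx = extract_features(t1v, t2v, m1, m2, fb)
                rows[p.patient_id] = fx.values
                volumes[p.patient_id] = float(m2.sum() * np.prod(target))
                if not manifest_written:
                    _write_json(self.out / "feature_manifest.json", fx.manifest)
                    manifest_written = True
            df = pd.DataFrame.from_dict(rows, orient="index")
            df.index.name = "patient_id"
            df.to_csv(self.out / f"features_{tag}.csv")
        pd.Series(volumes, name="volume_mm3").rename_axis("patient_id").to_csv(vol_f)
        key_f.write_text(key)
        self._record("extract", [f_tr, f_va, vol_f])

    # ------------------------------------------------------------- prognostic
    def _load_tables(self, tag: str) -> dict[str, pd.DataFrame]:
        d = self.out / "data" / tag
        return {
            name: pd.read_csv(d / f"{name}.csv", index_col="patient_id")
            for name in ("clinical", "vasari", "outcomes")
        }

    def _blocks(self, tag: str):
        tables = self._load_tables(tag)
        feats = pd.read_csv(self.out / f"features_{tag}.csv", index_col="patient_id")
        vas_dm = vasari.encode_for_model(vasari.recode(tables["vasari"]))
        clin = tables["clinical"].copy()
        clin["age_over70"] = (clin["age"] > 70).astype(int)
        clin["mgmt_methylated"] = tables["outcomes"]["MGMT"]
        sv = tables["outcomes"][["time", "event"]]
        return feats, vas_dm, clin, sv, tables["outcomes"]

    def prognostic(self) -> None:
        cfg = self.config["prognostic"]
        feats_tr, vas_tr, clin_tr, surv_tr, _ = self._blocks("train")
        feats_va, vas_va, clin_va, surv_va, _ = self._blocks("val")

        # radiomics block: z-score transfer, drop degenerate, screen, eliminate
        keep = [c for c in feats_tr.columns if feats_tr[c].std() > 0]
        mu, sd = feats_tr[keep].mean(), feats_tr[keep].std()
        r_tr = (feats_tr[keep] - mu) / sd
        r_va = (feats_va[keep] - mu) / sd
        screened, upv = surv.univariate_cox_screen(
            r_tr, surv_tr, alpha=cfg["screen_alpha"], return_pvalues=True
        )
        screened = sorted(screened, key=lambda c: (upv[c], c))[: cfg["max_radiomics_candidates"]]
        survivors = surv.eliminate_correlated(
            r_tr[screened], threshold=cfg["correlation_threshold"],
            keep_scores={c: -upv[c] for c in screened},
        )
        # keep events-per-variable sane for the multivariable fit
        n_events = int(surv_tr["event"].sum())
        survivors = sorted(survivors, key=lambda c: (upv[c], c))[: max(1, n_events // 2)]
        model_rad = surv.backward_eliminate(r_tr[survivors], surv_tr,
                                            alpha=cfg["removal_alpha"])

        # VASARI block
        vas_cols = [c for c in vas_tr.columns if vas_tr[c].std() > 0]
        v_tr = vas_tr[vas_cols].dropna()
        v_screen = surv.univariate_cox_screen(v_tr, surv_tr.loc[v_tr.index],
                                              alpha=cfg["screen_alpha"])
        n_ev_v = int(surv_tr.loc[v_tr.index, "event"].sum())
        v_screen = v_screen[: max(1, n_ev_v // 2)]
        model_vas = surv.backward_eliminate(v_tr[v_screen], surv_tr.loc[v_tr.index],
                                            alpha=cfg["removal_alpha"])

        # clinical block (all covariates entered; on separation in very small
        # cohorts, covariates are dropped from the end of the declared list)
        clin_cc = clin_tr.dropna(subset=["mgmt_methylated"])
        try:
            model_cli = surv.clinical_model(clin_cc, surv_tr)
        except ValueError as exc:
            log.warning("full clinical model failed (%s); reducing", exc)
            cov = list(surv.CLINICAL_COVARIATES)
            model_cli = surv.CoxModel(beta={})
            while cov:
                try:
                    model_cli = surv.fit_cox(clin_cc[cov],
                                             surv_tr.loc[clin_cc.index])
                    break
                except ValueError:
                    cov.pop()

        pis_tr = {
            "vasari": surv.compute_pi(model_vas, v_tr),
            "radiomics": surv.compute_pi(model_rad, r_tr),
            "clinical": surv.compute_pi(model_cli, clin_tr.dropna(subset=["mgmt_methylated"])),
        }
        vas_va_c = vas_va.reindex(columns=vas_tr.columns).dropna()
        pis_va = {
            "vasari": surv.compute_pi(model_vas, vas_va_c),
            "radiomics": surv.compute_pi(model_rad, r_va),
            "clinical": surv.compute_pi(model_cli, clin_va.dropna(subset=["mgmt_methylated"])),
        }

        models: dict[str, surv.CoxModel] = {
            "model1_vasari": model_vas,
            "model2_radiomics": model_rad,
            "model3_clinical": model_cli,
        }
        combos = {
            "model4_vasari_radiomics": ["vasari", "radiomics"],
            "model5_vasari_clinical": ["vasari", "clinical"],
            "model6_radiomics_clinical": ["radiomics", "clinical"],
            "model7_integrated": ["vasari", "radiomics", "clinical"],
        }
        stack_pi_tr, stack_pi_va = {}, {}
        for name, parts in combos.items():
            comp_tr = {p: pis_tr[p] for p in parts}
            try:
                models[name] = surv.stack_pi(comp_tr, surv_tr)
            except ValueError as exc:
                log.warning("stacking %s failed: %s", name, exc)
                continue
            df_tr = pd.DataFrame(comp_tr).dropna()
            df_va = pd.DataFrame({p: pis_va[p] for p in parts}).dropna()
            stack_pi_tr[name] = surv.compute_pi(models[name], df_tr)
            stack_pi_va[name] = surv.compute_pi(models[name], df_va)

        all_pis_tr = {
            "model1_vasari": pis_tr["vasari"],
            "model2_radiomics": pis_tr["radiomics"],
            "model3_clinical": pis_tr["clinical"],
            **stack_pi_tr,
        }
        all_pis_va = {
            "model1_vasari": pis_va["vasari"],
            "model2_radiomics": pis_va["radiomics"],
            "model3_clinical": pis_va["clinical"],
            **stack_pi_va,
        }

        report: dict = {"models": {}, "c_index": {}}
        rng = np.random.default_rng([self.seed, 41])
        for name, model in models.items():
            report["models"][name] = {
                "features": model.feature_ids,
                "beta": model.beta,
                "hazard_ratios": model.hazard_ratios,
                "pvalues": model.pvalues,
                "n_train": int(all_pis_tr[name].notna().sum()),
            }
            entry = {}
            for tag, pis, sv in [("train", all_pis_tr, surv_tr), ("val", all_pis_va, surv_va)]:
                pi = pis.get(name)
                if pi is None or pi.std() == 0:
                    entry[tag] = None
                    continue
                c, ci = surv.harrell_c(pi, sv, n_boot=cfg["c_index_bootstrap"],
                                       seed=int(rng.integers(2**31)))
                entry[tag] = {"c_index": c, "ci95": list(ci), "n": int(len(pi))}
            report["c_index"][name] = entry

        # validation diagnostics for the integrated model
        final = "model7_integrated"
        if final in stack_pi_va:
            slope, slope_p = surv.calibration_slope(stack_pi_va[final], surv_va)
            df_va = pd.DataFrame({p: pis_va[p] for p in combos[final]}).dropna()
            try:
                mis_p = surv.misspecification_test(df_va, models[final], surv_va)
            except ValueError as exc:
                log.warning("misspecification test unavailable: %s", exc)
                mis_p = float("nan")
            split = surv.km_split(
                stack_pi_tr[final], surv_tr, stack_pi_va[final], surv_va,
                percentile=cfg["km_percentile"],
            )
            report["validation"] = {
                "calibration_slope": slope,
                "calibration_slope_p": slope_p,
                "misspecification_p": mis_p,
                "km_threshold": split.threshold,
                "km_logrank_p": split.logrank_p,
            }
            km_rows = []
            for cohort, curves in split.observed.items():
                for gname, df in curves.items():
                    for t, s in df["S"].items():
                        km_rows.append({"cohort": cohort, "group": gname,
                                        "kind": "observed", "time": t, "S": s})
            for cohort, curves in split.predicted.items():
                for gname, df in curves.items():
                    for t, s in df["S"].items():
                        km_rows.append({"cohort": cohort, "group": gname,
                                        "kind": "predicted", "time": t, "S": s})
            pd.DataFrame(km_rows).to_csv(self.out / "km_curves.csv", index=False)

        # volume-surrogacy check on the selected radiomics features
        volumes = pd.read_csv(self.out / "volumes.csv", index_col="patient_id")["volume_mm3"]
        if model_rad.feature_ids:
            volcorr = surv.volume_correlation_check(
                r_tr[model_rad.feature_ids], volumes
            )
            volcorr.to_csv(self.out / "volume_correlation.csv")

        blocks = {"vasari": v_tr, "clinical": clin_tr[surv.CLINICAL_COVARIATES].dropna()}
        if model_rad.feature_ids:
            blocks["radiomics"] = r_tr[model_rad.feature_ids]
        surv.cross_block_correlation(blocks).to_csv(
            self.out / "cross_block_correlation.csv", index=False
        )

        _write_json(self.out / "prognostic_report.json", report)
        for name, model in models.items():
            model.to_json(self.out / f"cox_{name}.json")
        self._record("prognostic",
                     [self.out / "prognostic_report.json", self.out / "km_curves.csv"])

    # ------------------------------------------------------------- predictive
    def predictive(self) -> None:
        cfg = self.config["predictive"]
        feats_tr, vas_tr, _, _, out_tr = self._blocks("train")
        feats_va, vas_va, _, _, out_va = self._blocks("val")
        rng = np.random.default_rng([self.seed, 42])
        summary: dict = {}
        for marker in cfg["markers"]:
            y_tr = out_tr[marker].dropna().astype(int)
            y_va = out_va[marker].dropna().astype(int)
            if y_tr.nunique() < 2 or y_va.nunique() < 2:
                log.warning("marker %s lacks both classes; skipped", marker)
                continue
            marker_res = {}
            arm_probs_va = {}
            for arm, X_all_tr, X_all_va in [
                ("radiomics", feats_tr, feats_va),
                ("vasari", vas_tr.fillna(0.0), vas_va.reindex(columns=vas_tr.columns).fillna(0.0)),
            ]:
                X = X_all_tr.loc[y_tr.index.intersection(X_all_tr.index)]
                y = y_tr.loc[X.index]
                X = X.loc[:, X.std() > 0]
                keep = cls.eliminate_correlated_by_auc(
                    X, y, threshold=cfg["correlation_threshold"]
                )
                mu, sd = X[keep].mean(), X[keep].std()
                Xz = (X[keep] - mu) / sd
                top, _hist = cls.rf_importance_rank(
                    Xz, y, n_iter=cfg["n_iter_importance"],
                    seed=int(rng.integers(2**31)),
                )
                (Xtr, ytr), (Xte, yte) = cls.stratified_split(
                    Xz[top], y, ratio=cfg["split_ratio"], seed=int(rng.integers(2**31))
                )
                families = ("xgboost", "random_forest", "logistic_regression")
                override = cfg.get("vasari_family_overrides", {}).get(marker)
                if arm == "vasari" and override:
                    families = (override,)
                ranked = cls.model_search(
                    Xtr, ytr, Xte, yte, families=families,
                    n_iter=cfg["n_iter_search"], seed=int(rng.integers(2**31)),
                )
                top5 = ranked[: cfg["top_k_models"]]
                evald = cls.repeated_split_eval(
                    top5, Xz[top], y, n_repeats=cfg["n_repeats"],
                    ratio=cfg["split_ratio"], seed=int(rng.integers(2**31)),
                )
                evald.drop(columns="aucs").to_csv(
                    self.out / f"model_ranking_{marker}_{arm}.csv", index=False
                )
                best = top5[int(evald.iloc[0]["rank_in_search"])]
                # winner refit on the full training-center cohort, then frozen
                est = cls.build_estimator(best, seed=int(rng.integers(2**31)))
                est.fit(Xz[top].to_numpy(float), y.to_numpy(int))
                Xv = X_all_va.loc[y_va.index.intersection(X_all_va.index)]
                Xvz = ((Xv.reindex(columns=keep).fillna(0.0) - mu) / sd)[top]
                probs = est.predict_proba(Xvz.to_numpy(float))[:, 1]
                probs = pd.Series(probs, index=Xvz.index)
                yv = y_va.loc[probs.index]
                auc, ci = cls.bootstrap_auc_ci(
                    yv, probs.to_numpy(), n_boot=cfg["n_bootstrap"],
                    seed=int(rng.integers(2**31)),
                )
                arm_probs_va[arm] = probs
                marker_res[arm] = {
                    "selected_features": top,
                    "winner_family": best.family,
                    "winner_params": best.params,
                    "search_auc": best.mean_auc,
                    "repeated_split_mean_auc": float(evald.iloc[0]["mean_auc"]),
                    "validation_auc": auc,
                    "validation_auc_ci95": list(ci),
                }
                het = cls.heterogeneity_histograms(Xz[top], y)
                het.to_csv(self.out / f"heterogeneity_{marker}_{arm}.csv")

            common = arm_probs_va["radiomics"].index.intersection(
                arm_probs_va["vasari"].index
            )
            ens = cls.ensemble_average(
                arm_probs_va["radiomics"].loc[common].to_numpy(),
                arm_probs_va["vasari"].loc[common].to_numpy(),
            )
            auc, ci = cls.bootstrap_auc_ci(
                y_va.loc[common], ens, n_boot=cfg["n_bootstrap"],
                seed=int(rng.integers(2**31)),
            )
            marker_res["ensemble"] = {"validation_auc": auc,
                                      "validation_auc_ci95": list(ci)}
            roc_df = pd.DataFrame({
                "patient_id": common,
                "label": y_va.loc[common].to_numpy(),
                "prob_radiomics": arm_probs_va["radiomics"].loc[common].to_numpy(),
                "prob_vasari": arm_probs_va["vasari"].loc[common].to_numpy(),
                "prob_ensemble": ens,
            })
            roc_df.to_csv(self.out / f"predictions_{marker}.csv", index=False)
            summary[marker] = marker_res
        _write_json(self.out / "predictive_report.json", summary)
        self._record("predictive", [self.out / "predictive_report.json"])

    # ------------------------------------------------------------------ report
    def report(self) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        d = self.out / "report"
        d.mkdir(exist_ok=True)
        prog_f = self.out / "prognostic_report.json"
        artifacts = []
        if prog_f.exists():
            prog = json.loads(prog_f.read_text())
            rows = [(name, entry) for name, entry in prog["c_index"].items()]
            fig, ax = plt.subplots(figsize=(6, 0.6 * len(rows) + 1))
            for k, (name, entry) in enumerate(rows):
                for off, tag, color in [(-0.12, "train", "C0"), (0.12, "val", "C3")]:
                    e = entry.get(tag)
                    if not e:
                        continue
                    ax.errorbar(
                        e["c_index"], k + off,
                        xerr=[[e["c_index"] - e["ci95"][0]], [e["ci95"][1] - e["c_index"]]],
                        fmt="o", color=color, label=tag if k == 0 else None,
                    )
            ax.set_yticks(range(len(rows)))
            ax.set_yticklabels([r[0] for r in rows], fontsize=8)
            ax.axvline(0.5, color="gray", lw=0.8, ls=":")
            ax.set_xlabel("Harrell's C-index (95% CI)")
            ax.legend(fontsize=8)
            fig.tight_layout()
            fig.savefig(d / "c_index_forest.svg")
            plt.close(fig)
            artifacts.append(d / "c_index_forest.svg")

            km_f = self.out / "km_curves.csv"
            if km_f.exists():
                km = pd.read_csv(km_f)
                fig, axes = plt.subplots(1, km["cohort"].nunique(), figsize=(9, 3.5),
                                         squeeze=False)
                for ax, (cohort, sub) in zip(axes[0], km.groupby("cohort")):
                    for (group, kind), ss in sub.groupby(["group", "kind"]):
                        style = "-" if kind == "observed" else "--"
                        color = "C3" if group == "high" else "C0"
                        ax.step(ss["time"], ss["S"], style, color=color,
                                where="post", label=f"{group} {kind}")
                    ax.set_title(f"{cohort} cohort", fontsize=9)
                    ax.set_xlabel("months")
                    ax.set_ylabel("survival")
                    ax.legend(fontsize=6)
                fig.tight_layout()
                fig.savefig(d / "km_risk_groups.svg")
                plt.close(fig)
                artifacts.append(d / "km_risk_groups.svg")
        else:
            log.warning("no prognostic artifacts; section skipped")

        pred_f = self.out / "predictive_report.json"
        if pred_f.exists():
            pred = json.loads(pred_f.read_text())
            if pred:
                fig, ax = plt.subplots(figsize=(6, 3.5))
                labels, vals, errs = [], [], []
                for marker, arms in pred.items():
                    for arm, e in arms.items():
                        if "validation_auc" not in e:
                            continue
                        labels.append(f"{marker}:{arm}")
                        vals.append(e["validation_auc"])
                        ci = e["validation_auc_ci95"]
                        errs.append([e["validation_auc"] - ci[0], ci[1] - e["validation_auc"]])
                ax.bar(range(len(vals)), vals,
                       yerr=np.array(errs).T if errs else None, color="C0")
                ax.set_xticks(range(len(labels)))
                ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=7)
                ax.axhline(0.5, color="gray", lw=0.8, ls=":")
                ax.set_ylabel("validation AUC (95% CI)")
                fig.tight_layout()
                fig.savefig(d / "predictive_auc.svg")
                plt.close(fig)
                artifacts.append(d / "predictive_auc.svg")
        else:
            log.warning("no predictive artifacts; section skipped")
        self._record("report", artifacts, hash_artifacts=False)

    # --------------------------------------------------------------- plumbing
    def _record(self, stage: str, artifacts, cached: bool = False,
                hash_artifacts: bool = True) -> None:
        self.manifest["stages"].append({"stage": stage, "cached": cached})
        if hash_artifacts:
            for a in artifacts:
                a = Path(a)
                if a.exists() and a.suffix in {".csv", ".json"}:
                    self.manifest["artifacts"][str(a.relative_to(self.out))] = _sha256(a)

    def write_manifest(self) -> Path:
        path = self.out / "manifest.json"
        _write_json(path, self.manifest)
        return path


STAGES = ["simulate", "extract", "prognostic", "predictive", "report"]


def run(config: dict, stages: list[str] | None = None) -> dict:
    """Execute the requested stages (default: all) and write the manifest."""
    study = StudyRun(config)
    for stage in stages or STAGES:
        if stage not in STAGES:
            raise ValueError(f"unknown stage: {stage} (choose from {STAGES})")
        getattr(study, stage)()
    study.write_manifest()
    return study.manifest
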