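"""End-to-end orchestration: simulate -> QC -> ALFF -> select -> classify
-> permute -> brain-behavior, emitting one JSON report."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import alff as alff_mod
from . import classify as clf_mod
from . import selection as sel_mod
from . import stats as stats_mod
from .alff import FeatureMatrix, exclude_high_motion
from .synthetic import Cohort, SyntheticConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "cohort_to_features",
           "nested_loocv_evaluate", "validate_report"]


@dataclass
class RunConfig:
    """Everything one reproducible run needs, seeds included."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    band: tuple[float, float] = (0.01, 0.08)
    fd_threshold: float = 0.2
    fd_statistic: str = "mean"
    alpha: float = 0.05
    selection_mode: str = "pooled"        # "pooled" (leaky, as published) | "nested"
    scale_mode: str = "minmax"            # "minmax" | "zscore"
    stage1_unit: str = "subject"
    cv_scheme: str = "subject"            # "subject" | "scan"
    C: float = 1.0
    B: int = 1000
    perm_pairing: str = "subject"         # "subject" | "scan"
    perm_scope: str = "final_features"    # "final_features" | "full_pipeline"
    perm_seed: int = 7
    q: float = 0.05
    brain_behavior_regions: str = "selected"   # "selected" | "all"
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        syn = raw.pop("synthetic", {})
        return cls(synthetic=SyntheticConfig(**syn), **raw)


def cohort_to_features(
    cohort: Cohort,
    band: tuple[float, float] = (0.01, 0.08),
    subjects: list | None = None,
) -> FeatureMatrix:
    """Region-wise standardized ALFF feature matrix for (retained) subjects."""
    keep = set(subjects) if subjects is not None else {
        sid for sid, _ in cohort.images
    }
    vectors = {}
    for (sid, cond), img in cohort.images.items():
        if sid not in keep:
            continue
        m = alff_mod.compute_voxel_alff(img, band=band)
        m = alff_mod.standardize_alff(m, img.mask)
        vectors[(sid, cond)] = alff_mod.region_average(m, cohort.atlas)
    return alff_mod.build_feature_matrix(vectors)


def _final_weights(fm_final: FeatureMatrix, C: float, scale_mode: str):
    """Hyperplane trained on all rows; positive weight = higher post ALFF."""
    X = fm_final.values.to_numpy(dtype=float)
    X = sel_mod.FeatureScaler(scale_mode).fit(X).transform(X)
    model = clf_mod.train_linear_svm(X, fm_final.labels, C=C)
    return [
        {"region": int(r), "weight": float(w)}
        for r, w in zip(fm_final.region_labels, model.weights)
    ]


def nested_loocv_evaluate(fm: FeatureMatrix, behavior, cfg: RunConfig):
    """Re-run both selection stages inside each outer leave-one-subject-out
    fold; returns (metrics, per-fold selected regions)."""
    sids_all = fm.subject_ids
    y = fm.labels
    uniq = np.unique(sids_all)
    pred = np.empty(y.size, dtype=int)
    dec = np.empty(y.size, dtype=float)
    fold_regions = {}
    for sid in uniq:
        test_rows = np.flatnonzero(sids_all == sid)
        train_rows = np.flatnonzero(sids_all != sid)
        fm_train = FeatureMatrix(fm.values.iloc[train_rows].reset_index(drop=True),
                                 y[train_rows], sids_all[train_rows])
        stage1 = sel_mod.stage1_select(fm_train, alpha=cfg.alpha,
                                       unit=cfg.stage1_unit)
        if not stage1:
            stage1 = [int(r) for r in fm.region_labels]
        cols = [r for r in fm.region_labels if r in set(stage1)]
        cfmt_tr = sel_mod.cfmt_per_sample(behavior, sids_all[train_rows],
                                          y[train_rows])
        cfmt_te = sel_mod.cfmt_per_sample(behavior, sids_all[test_rows],
                                          y[test_rows])
        Ytr = fm.values[cols].to_numpy(dtype=float)[train_rows]
        Yte = fm.values[cols].to_numpy(dtype=float)[test_rows]
        if np.ptp(cfmt_tr) == 0:
            mu = Ytr.mean(axis=0)
            Rtr, Rte = Ytr - mu, Yte - mu
        else:
            A = np.column_stack([np.ones_like(cfmt_tr), cfmt_tr])
            beta, *_ = np.linalg.lstsq(A, Ytr, rcond=None)
            Rtr = Ytr - A @ beta
            Rte = Yte - np.column_stack([np.ones_like(cfmt_te), cfmt_te]) @ beta
        fm_tr_resid = FeatureMatrix(
            pd.DataFrame(Rtr, columns=cols), y[train_rows], sids_all[train_rows])
        rfe = sel_mod.rfe_select(fm_tr_resid, C=cfg.C, scheme=cfg.cv_scheme,
                                 scale=cfg.scale_mode)
        sel_cols = rfe.stage2_regions
        fold_regions[int(sid)] = [int(r) for r in sel_cols]
        ix = [cols.index(r) for r in sel_cols]
        scaler = sel_mod.FeatureScaler(cfg.scale_mode).fit(Rtr[:, ix])
        model = clf_mod.train_linear_svm(scaler.transform(Rtr[:, ix]),
                                         y[train_rows], C=cfg.C)
        d = model.decision_values(scaler.transform(Rte[:, ix]))
        pred[test_rows] = np.where(d >= 0, 1, -1)
        dec[test_rows] = d
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == -1) & (y == 1)).sum())
    tn = int(((pred == -1) & (y == -1)).sum())
    fp = int(((pred == 1) & (y == -1)).sum())
    accuracy, sensitivity, specificity = clf_mod.compute_metrics(tp, fn, tn, fp)
    auc, roc_points = clf_mod.roc_auc(dec, y)
    metrics = clf_mod.ClassificationMetrics(tp, fn, tn, fp, accuracy,
                                            sensitivity, specificity, auc,
                                            roc_points, pred, dec)
    return metrics, fold_regions


def _honest_permutation(fm: FeatureMatrix, behavior, cfg: RunConfig,
                        observed: float) -> clf_mod.PermutationResult:
    """Re-run the full selection under each label permutation (subject-paired
    flips only, to keep the design balanced)."""
    if cfg.perm_pairing != "subject":
        raise ValueError("full-pipeline permutation requires subject pairing")
    rng = np.random.default_rng(cfg.perm_seed)
    y = fm.labels
    null = np.empty(cfg.B)
    for b in range(cfg.B):
        yb = y.copy()
        for sid in np.unique(fm.subject_ids):
            if rng.random() < 0.5:
                yb[fm.subject_ids == sid] *= -1
        fm_b = FeatureMatrix(fm.values.copy(), yb, fm.subject_ids.copy())
        try:
            sel_b, fm_resid_b = sel_mod.run_selection(
                fm_b, behavior, alpha=cfg.alpha, C=cfg.C,
                scheme=cfg.cv_scheme, scale=cfg.scale_mode)
            fm_fin = fm_resid_b.subset_regions(sel_b.stage2_regions)
            pred, _ = clf_mod.loocv_predictions(
                fm_fin.values.to_numpy(dtype=float), yb, fm_fin.subject_ids,
                scheme=cfg.cv_scheme, C=cfg.C, train_labels=yb,
                scale=cfg.scale_mode)
            null[b] = (pred == y).mean()
        except RuntimeError:
            null[b] = 0.5  # selection emptied the feature set: chance model
    n_ge = int((null >= observed - 1e-12).sum())
    return clf_mod.PermutationResult(observed, null, n_ge / cfg.B,
                                     (n_ge + 1) / (cfg.B + 1), cfg.B,
                                     cfg.perm_seed)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order and return the validated JSON report."""
    cohort = generate_cohort(cfg.synthetic)

    retained, exclusion_log = exclude_high_motion(
        cohort.motion, cfg.fd_threshold, statistic=cfg.fd_statistic)
    if not retained:
        raise RuntimeError("motion QC excluded every subject")

    fm = cohort_to_features(cohort, band=cfg.band, subjects=retained)
    behavior = cohort.behavior[cohort.behavior.subject_id.isin(retained)] \
        .reset_index(drop=True)

    sel, fm_resid = sel_mod.run_selection(
        fm, behavior, alpha=cfg.alpha, C=cfg.C, scheme=cfg.cv_scheme,
        scale=cfg.scale_mode)
    fm_final = fm_resid.subset_regions(sel.stage2_regions)
    X_final = fm_final.values.to_numpy(dtype=float)

    if cfg.selection_mode == "pooled":
        metrics = clf_mod.loocv_evaluate(
            X_final, fm_final.labels, fm_final.subject_ids,
            scheme=cfg.cv_scheme, C=cfg.C, scale=cfg.scale_mode)
        fold_regions = None
    elif cfg.selection_mode == "nested":
        metrics, fold_regions = nested_loocv_evaluate(fm, behavior, cfg)
    else:
        raise ValueError(f"unknown selection mode {cfg.selection_mode!r}")

    if cfg.perm_scope == "final_features":
        perm = clf_mod.permutation_test(
            X_final, fm_final.labels, fm_final.subject_ids, B=cfg.B,
            seed=cfg.perm_seed, scheme=cfg.cv_scheme, pairing=cfg.perm_pairing,
            C=cfg.C, scale=cfg.scale_mode)
    elif cfg.perm_scope == "full_pipeline":
        perm = _honest_permutation(fm, behavior, cfg, metrics.accuracy)
    else:
        raise ValueError(f"unknown permutation scope {cfg.perm_scope!r}")

    behavior_stats = stats_mod.behavior_group_stats(behavior)

    bb_regions = sel.stage2_regions if cfg.brain_behavior_regions == "selected" \
        else [int(r) for r in fm.region_labels]
    sids, pre, post = fm.paired_arrays(bb_regions)
    feature_deltas = pd.DataFrame(post - pre, index=sids, columns=bb_regions)
    beh_idx = behavior.set_index("subject_id").loc[sids]
    behavior_deltas = pd.DataFrame({
        "cfmt": beh_idx.cfmt_post - beh_idx.cfmt_pre,
        "ret": beh_idx.ret_post - beh_idx.ret_pre,
    }, index=sids)
    bb_table = stats_mod.correlate_alff_behavior(feature_deltas,
                                                 behavior_deltas, q=cfg.q)

    report = {
        "config": cfg.to_dict(),
        "qc": {
            "retained_subjects": [int(s) for s in retained],
            "n_retained": len(retained),
            "excluded": exclusion_log,
        },
        "counts": {
            "n_scans": int(len(fm.values)),
            "n_regions": int(fm.region_labels.size),
            "n_stage1": len(sel.stage1_regions),
            "n_final": len(sel.stage2_regions),
        },
        "selection": {
            "mode": cfg.selection_mode,
            "stage1_regions": [int(r) for r in sel.stage1_regions],
            "final_regions": [int(r) for r in sel.stage2_regions],
            "accuracy_trace": [float(a) for a in sel.accuracy_trace],
            "removed_per_round": [[int(r) for r in rnd]
                                  for rnd in sel.removed_per_round],
            "per_fold_regions": fold_regions,
        },
        "weights": _final_weights(fm_final, cfg.C, cfg.scale_mode),
        "metrics": metrics.to_dict(),
        "roc_points": [[float(a), float(b)] for a, b in metrics.roc_points],
        "permutation": perm.to_dict(),
        "behavior_stats": behavior_stats.to_dict(orient="records"),
        "brain_behavior": bb_table.to_dict(orient="records"),
        "truth": cohort.truth,
    }
    validate_report(report)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fm.to_tsv(out / "feature_matrix.tsv")
        sel.to_json(out / "selection.json")
        pd.DataFrame({"null_accuracy": perm.null_accuracies}) \
            .to_csv(out / "null_accuracies.csv", index=False)
        pd.DataFrame(metrics.roc_points, columns=["fpr", "tpr"]) \
            .to_csv(out / "roc_points.csv", index=False)
        bb_table.to_csv(out / "brain_behavior.csv", index=False)
        behavior.to_csv(out / "behavior.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report


def _check(value, schema, path="report"):
    t = schema.get("type")
    ok = {
        "object": dict, "array": list, "string": str, "boolean": bool,
    }
    if t == "number":
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValueError(f"{path}: expected number, got {type(value).__name__}")
    elif t == "integer":
        if not isinstance(value, int) or isinstance(value, bool):
            raise ValueError(f"{path}: expected integer, got {type(value).__name__}")
    elif t in ok:
        if not isinstance(value, ok[t]):
            raise ValueError(f"{path}: expected {t}, got {type(value).__name__}")
    if t == "object":
        for key in schema.get("required", []):
            if key not in value:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value and value[key] is not None:
                _check(value[key], sub, f"{path}.{key}")
    if t == "array" and "items" in schema:
        for i, item in enumerate(value):
            _check(item, schema["items"], f"{path}[{i}]")


def validate_report(report: dict) -> None:
    """Check the report against the bundled schema; raises on violation."""
    schema = json.loads(
        resources.files("alffpipe").joinpath("report_schema.json").read_text())
    _check(report, schema)
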