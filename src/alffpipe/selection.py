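"""Two-stage feature selection.

Stage 1 screens regions with a paired t-test run in a leave-one-out fashion
(union of regions surviving p < alpha in any iteration), after which the
surviving features are residualized against the CFMT confound.  Stage 2 is
an accuracy-driven recursive feature elimination: per round, compute the
LOOCV-SVM accuracy of the current set (accuracy_0), then the accuracy
without each single feature (accuracy_i), and delete in one batch every
feature whose removal does not decrease accuracy; stop when no removal
keeps accuracy, when the batch would reduce the joint accuracy (the batch
is reverted), or when one feature remains.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .alff import FeatureMatrix
from .classify import _scale_apply, _scale_fit, predict_prepared, prepare_folds

__all__ = [
    "SelectionResult",
    "FeatureScaler",
    "paired_t_test",
    "stage1_select",
    "regress_out_confound",
    "rescale_features",
    "rfe_select",
    "run_selection",
    "cfmt_per_sample",
]

_EPS = 1e-12


@dataclass
class SelectionResult:
    """Surviving regions per stage plus the RFE accuracy trace."""

    stage1_regions: list
    stage2_regions: list
    accuracy_trace: list
    removed_per_round: list

    def __post_init__(self):
        if not set(self.stage2_regions) <= set(self.stage1_regions):
            raise ValueError("stage2 regions must be a subset of stage1 regions")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "stage1_regions": [int(r) for r in self.stage1_regions],
            "stage2_regions": [int(r) for r in self.stage2_regions],
            "accuracy_trace": self.accuracy_trace,
            "removed_per_round": [[int(r) for r in rnd]
                                  for rnd in self.removed_per_round],
        }, indent=2))

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        raw = json.loads(Path(path).read_text())
        return cls(raw["stage1_regions"], raw["stage2_regions"],
                   raw["accuracy_trace"], raw["removed_per_round"])


def paired_t_test(pre: np.ndarray, post: np.ndarray):
    """Paired t on differences post - pre; two-sided p with n-1 df."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre/post must have equal lengths")
    n = pre.shape[0]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        warnings.warn("zero variance of paired differences; p undefined",
                      stacklevel=2)
        return np.inf * np.sign(d.mean()), np.nan
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def _paired_t_matrix(diffs: np.ndarray):
    """Vectorized paired t over columns of a pairs x regions difference matrix."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[sd == 0] = np.where(np.abs(mean[sd == 0]) < _EPS, 1.0, np.nan)
    return t, p


def stage1_select(fm: FeatureMatrix, alpha: float = 0.05,
                  unit: str = "subject") -> list[int]:
    """Union over LOO iterations of regions with paired-t p < alpha.

    Each iteration holds out one subject (holding out a single scan leaves
    its partner unpaired, so scan-level iteration reduces to the same set of
    training pairs and is treated identically).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if unit not in ("subject", "scan"):
        raise ValueError(f"unknown leave-out unit {unit!r}")
    sids, pre, post = fm.paired_arrays()
    if sids.size < 4:
        raise ValueError("need at least 3 training pairs per iteration")
    diffs = post - pre
    regions = fm.region_labels
    survivors: set[int] = set()
    for i in range(sids.size):
        train = np.delete(diffs, i, axis=0)
        _, p = _paired_t_matrix(train)
        survivors |= set(regions[np.nan_to_num(p, nan=1.0) < alpha].tolist())
    return sorted(survivors)


def cfmt_per_sample(behavior, subject_ids, labels) -> np.ndarray:
    """Each scan row's own-session CFMT score from the behavior table."""
    beh = behavior.set_index("subject_id")
    out = np.empty(len(subject_ids), dtype=float)
    for i, (sid, lab) in enumerate(zip(subject_ids, labels)):
        col = "cfmt_post" if lab == 1 else "cfmt_pre"
        out[i] = beh.at[sid, col]
    return out


def regress_out_confound(fm: FeatureMatrix, cfmt: np.ndarray) -> FeatureMatrix:
    """Replace each feature column by its residual on CFMT (with intercept)."""
    cfmt = np.asarray(cfmt, dtype=float)
    if cfmt.shape != (len(fm.values),):
        raise ValueError("need exactly one CFMT value per sample row")
    Y = fm.values.to_numpy(dtype=float)
    if np.ptp(cfmt) == 0:
        warnings.warn("constant CFMT: residualization reduces to mean-centering",
                      stacklevel=2)
        resid = Y - Y.mean(axis=0)
    else:
        A = np.column_stack([np.ones_like(cfmt), cfmt])
        beta, *_ = np.linalg.lstsq(A, Y, rcond=None)
        resid = Y - A @ beta
    out = fm.values.copy()
    out.iloc[:, :] = resid
    return FeatureMatrix(out, fm.labels.copy(), fm.subject_ids.copy())


class FeatureScaler:
    """Per-column rescaling with parameters learned on training rows only.

    mode "minmax" maps the training range onto [0, 1] (constant columns map
    to 0.5 with a warning); mode "zscore" standardizes to zero mean, unit sd.
    Test rows may land outside [0, 1]; that is permitted.
    """

    def __init__(self, mode: str = "minmax"):
        if mode not in ("minmax", "zscore"):
            raise ValueError(f"unknown scaling mode {mode!r}")
        self.mode = mode
        self._params = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        self._params = _scale_fit(X, self.mode)
        if self._params[3].any():
            warnings.warn("constant feature column(s) during scaling",
                          stacklevel=2)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._params is None:
            raise RuntimeError("FeatureScaler not fitted")
        return _scale_apply(np.asarray(X, dtype=float), self._params)


def rescale_features(fm: FeatureMatrix, mode: str = "minmax") -> FeatureMatrix:
    """Rescale all columns using parameters from the full matrix."""
    scaler = FeatureScaler(mode).fit(fm.values.to_numpy(dtype=float))
    out = fm.values.copy()
    out.iloc[:, :] = scaler.transform(fm.values.to_numpy(dtype=float))
    return FeatureMatrix(out, fm.labels.copy(), fm.subject_ids.copy())


def rfe_select(
    fm: FeatureMatrix,
    C: float = 1.0,
    scheme: str = "subject",
    scale: str | None = "minmax",
    batch: bool = True,
) -> SelectionResult:
    """Accuracy-driven recursive feature elimination (batch removal).

    With ``batch=False`` a single feature (the one whose removal gives the
    highest accuracy, ties broken by lowest region label) is removed per
    round instead of the whole batch.
    """
    regions = [int(r) for r in fm.region_labels]
    if len(regions) < 1:
        raise ValueError("need at least one feature")
    y, sids = fm.labels, fm.subject_ids
    X = fm.values.to_numpy(dtype=float)
    # per-fold scaling is per-column, so one cache serves every subset
    prepared = prepare_folds(X, sids, scheme=scheme, scale=scale)
    col_of = {r: i for i, r in enumerate(regions)}

    def acc_of(cols: list[int]) -> float:
        ix = [col_of[r] for r in cols]
        pred, _ = predict_prepared(prepared, y, y.size, C=C, cols=ix)
        return float((pred == y).mean())

    current = list(regions)
    acc0 = acc_of(current)
    trace = [acc0]
    removed_per_round: list[list[int]] = []
    while len(current) > 1:
        acc_wo = {r: acc_of([c for c in current if c != r]) for r in current}
        removable = [r for r in current if acc_wo[r] >= acc0 - _EPS]
        if not removable:
            break
        if not batch:
            best = max(removable, key=lambda r: (acc_wo[r], -r))
            removable = [best]
        if len(removable) == len(current):
            # keep the single feature whose removal scored highest
            keep = max(current, key=lambda r: (acc_wo[r], -r))
            removable = [r for r in current if r != keep]
        tentative = [r for r in current if r not in set(removable)]
        new_acc = acc_of(tentative)
        if new_acc < acc0 - _EPS:
            break  # joint elimination reduces accuracy: revert and stop
        current = tentative
        acc0 = new_acc
        removed_per_round.append(sorted(removable))
        trace.append(acc0)
    return SelectionResult(stage1_regions=regions, stage2_regions=current,
                           accuracy_trace=trace,
                           removed_per_round=removed_per_round)


def run_selection(
    fm: FeatureMatrix,
    behavior,
    alpha: float = 0.05,
    C: float = 1.0,
    scheme: str = "subject",
    scale: str | None = "minmax",
    batch: bool = True,
) -> tuple[SelectionResult, FeatureMatrix]:
    """Stage 1 screening + CFMT residualization + RFE, on the full matrix.

    Returns the selection result and the residualized feature matrix
    restricted to the stage-1 survivors (input for final classification).
    """
    stage1 = stage1_select(fm, alpha=alpha)
    if not stage1:
        raise RuntimeError("stage-1 screening removed every region")
    fm1 = fm.subset_regions(stage1)
    cfmt = cfmt_per_sample(behavior, fm1.subject_ids, fm1.labels)
    fm_resid = regress_out_confound(fm1, cfmt)
    rfe = rfe_select(fm_resid, C=C, scheme=scheme, scale=scale, batch=batch)
    result = SelectionResult(stage1_regions=stage1,
                             stage2_regions=rfe.stage2_regions,
                             accuracy_trace=rfe.accuracy_trace,
                             removed_per_round=rfe.removed_per_round)
    return result, fm_resid
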