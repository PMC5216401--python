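"""Regression- and classification-validation statistics for QSAR-style models.

Implements the external-validation battery used to judge binding-affinity
and pose-RMSD regressors: plain and through-origin correlation statistics
(r2, k, k', r0(2), r0'(2)), Roy's rm(2) family, Lin's concordance correlation
coefficient, cross-validated q2, the Golbraikh/Tropsha-style pass/fail
criteria, and confusion-matrix statistics (Cooper statistics, MCC, Kubat's
G-mean) for qualitative top-pose selection.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np


__all__ = [
    "RegressionReport",
    "CriteriaReport",
    "ConfusionMatrix",
    "ClassificationReport",
    "regression_report",
    "q2_cross_validation",
    "criteria_battery",
    "pose_selection_confusion",
    "classification_report",
]


@dataclass
class RegressionReport:
    """Complete observed-vs-predicted statistics for one data set.

    ``q2`` is the squared Pearson correlation between observed and predicted
    values (the pairing used when a test set is reported next to a training
    r2); ``q2_f1`` is the predictive squared coefficient
    1 - sum((y - yhat)^2) / sum((y - mean(y))^2), reported alongside.
    """

    n: int
    r2: float
    q2: float
    q2_f1: float
    mae: float
    rmse: float
    s: float
    delta_max: float
    k: float
    k_prime: float
    r0_2: float
    r0_prime_2: float
    rm2: float
    rm2_prime: float
    rm2_avg: float
    rm2_delta: float
    ccc: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CriterionResult:
    name: str
    description: str
    value: float
    passed: bool


@dataclass
class CriteriaReport:
    criteria: list[CriterionResult]

    @property
    def overall(self) -> bool:
        return all(c.passed for c in self.criteria)

    def __getitem__(self, name: str) -> CriterionResult:
        for c in self.criteria:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "criteria": [asdict(c) for c in self.criteria],
        }

    def as_marks(self) -> dict[str, str]:
        """Render per-criterion verdicts as 'x' (pass) / '' (fail)."""
        return {c.name: ("x" if c.passed else "") for c in self.criteria}


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.fn, self.tn):
            if v < 0:
                raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ClassificationReport:
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    g_mean: float
    mcc_degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def _check_pair(y: np.ndarray, yhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.size} observed vs {yhat.size} predicted")
    if y.size < 3:
        raise ValueError("at least 3 observations required")
    if np.ptp(y) == 0:
        raise ValueError("observed values are constant; statistics undefined")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("inputs must be finite")
    return y, yhat


def _pearson_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sy = y - y.mean()
    sp = yhat - yhat.mean()
    denom = np.sqrt((sy**2).sum() * (sp**2).sum())
    if denom == 0:
        return 0.0
    return float(((sy * sp).sum() / denom) ** 2)


def regression_report(y: Sequence[float], yhat: Sequence[float]) -> RegressionReport:
    """Compute the full regression-validation report.

    Through-origin statistics follow the Golbraikh-Tropsha convention:
    k = sum(y*yhat)/sum(yhat^2) is the slope of observed regressed on
    predicted through the origin, r0_2 its determination coefficient
    around the observed mean; primed variants swap the roles.  rm2 uses
    |r2 - r0_2| under the radical so it stays defined when r0_2 > r2.
    CCC uses population (biased) moments.
    """
    y, yhat = _check_pair(np.asarray(y), np.asarray(yhat))
    n = y.size
    resid = y - yhat

    r2 = _pearson_r2(y, yhat)
    q2_f1 = 1.0 - float((resid**2).sum() / ((y - y.mean()) ** 2).sum())
    mae = float(np.abs(resid).mean())
    rmse = float(np.sqrt((resid**2).mean()))
    s = float(np.std(resid, ddof=1))
    delta_max = float(np.abs(resid).max())

    k = float((y * yhat).sum() / (yhat**2).sum())
    k_prime = float((y * yhat).sum() / (y**2).sum())
    r0_2 = 1.0 - float(((y - k * yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum())
    r0_prime_2 = 1.0 - float(
        ((yhat - k_prime * y) ** 2).sum() / ((yhat - yhat.mean()) ** 2).sum()
    )

    rm2 = r2 * (1.0 - np.sqrt(abs(r2 - r0_2)))
    rm2_prime = r2 * (1.0 - np.sqrt(abs(r2 - r0_prime_2)))
    rm2_avg = (rm2 + rm2_prime) / 2.0
    rm2_delta = abs(rm2 - rm2_prime)

    cov = float(np.mean((y - y.mean()) * (yhat - yhat.mean())))
    var_y = float(np.var(y))
    var_p = float(np.var(yhat))
    ccc = 2.0 * cov / (var_y + var_p + (y.mean() - yhat.mean()) ** 2)

    return RegressionReport(
        n=n, r2=r2, q2=r2, q2_f1=q2_f1, mae=mae, rmse=rmse, s=s,
        delta_max=delta_max, k=k, k_prime=k_prime, r0_2=r0_2,
        r0_prime_2=r0_prime_2, rm2=float(rm2), rm2_prime=float(rm2_prime),
        rm2_avg=float(rm2_avg), rm2_delta=float(rm2_delta), ccc=float(ccc),
    )


def _quantile_stratified_folds(
    y: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign folds so each fold samples the whole response range.

    Rows are ordered by response, walked in blocks of `folds`, and each
    block's members are dealt to a random permutation of the folds.
    """
    order = np.argsort(y, kind="stable")
    assign = np.empty(y.size, dtype=int)
    for start in range(0, y.size, folds):
        block = order[start:start + folds]
        assign[block] = rng.permutation(folds)[: block.size]
    return assign


def q2_cross_validation(
    X,
    y,
    trainer: Callable,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Cross-validated predictive coefficient q2cv = 1 - PRESS/SS.

    ``trainer(X_train, y_train)`` must return an object with ``predict``.
    Out-of-fold predictions are pooled; the total sum of squares is taken
    around the grand mean of y.  Fold assignment is seeded and stratified
    by response quantile.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if y.size < folds:
        raise ValueError(f"n={y.size} is smaller than folds={folds}")
    rng = np.random.default_rng(seed)
    if folds == y.size:
        assign = np.arange(y.size)  # leave-one-out
    else:
        assign = _quantile_stratified_folds(y, folds, rng)
    preds = np.empty_like(y)
    for f in range(folds):
        test = assign == f
        if not test.any():
            continue
        model = trainer(X[~test], y[~test])
        preds[test] = np.asarray(model.predict(X[test]), dtype=float).ravel()
    press = float(((y - preds) ** 2).sum())
    ss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss


def criteria_battery(
    train_report: RegressionReport,
    test_report: RegressionReport,
    q2cv: float | None = None,
    thresholds: dict | None = None,
) -> CriteriaReport:
    """Evaluate the stringent external-validation criteria.

    Defaults: q2cv > 0.5; test r2 > 0.6; one of the through-origin
    determination coefficients close to r2 ((r2-r0_2)/r2 < 0.1 or primed);
    a through-origin slope in [0.85, 1.15]; |r0_2 - r0'_2| < 0.3;
    rm2_avg > 0.5 with rm2_delta < 0.2; CCC > 0.85.  All thresholds are
    overridable through ``thresholds``.
    """
    th = {
        "q2cv_min": 0.5,
        "r2_min": 0.6,
        "r0_rel_max": 0.1,
        "k_lo": 0.85,
        "k_hi": 1.15,
        "r0_gap_max": 0.3,
        "rm2_avg_min": 0.5,
        "rm2_delta_max": 0.2,
        "ccc_min": 0.85,
    }
    if thresholds:
        th.update(thresholds)
    t = test_report
    results = []
    if q2cv is not None:
        results.append(CriterionResult(
            "q2cv", f"q2cv > {th['q2cv_min']}", q2cv, q2cv > th["q2cv_min"]))
    results.append(CriterionResult(
        "q2_external", f"test q2 (F1 form) > {th['q2cv_min']}",
        t.q2_f1, t.q2_f1 > th["q2cv_min"]))
    results.append(CriterionResult(
        "r2_test", f"test r2 > {th['r2_min']}", t.r2, t.r2 > th["r2_min"]))
    rel = (t.r2 - t.r0_2) / t.r2 if t.r2 > 0 else np.inf
    rel_p = (t.r2 - t.r0_prime_2) / t.r2 if t.r2 > 0 else np.inf
    results.append(CriterionResult(
        "r0_close", f"(r2-r0_2)/r2 < {th['r0_rel_max']} (either variant)",
        min(rel, rel_p),
        rel < th["r0_rel_max"] or rel_p < th["r0_rel_max"]))
    k_ok = th["k_lo"] <= t.k <= th["k_hi"]
    kp_ok = th["k_lo"] <= t.k_prime <= th["k_hi"]
    results.append(CriterionResult(
        "slope_k", f"{th['k_lo']} <= k or k' <= {th['k_hi']}",
        t.k if k_ok or not kp_ok else t.k_prime, k_ok or kp_ok))
    gap = abs(t.r0_2 - t.r0_prime_2)
    results.append(CriterionResult(
        "r0_gap", f"|r0_2 - r0'_2| < {th['r0_gap_max']}", gap,
        gap < th["r0_gap_max"]))
    results.append(CriterionResult(
        "rm2", f"rm2_avg > {th['rm2_avg_min']} and delta_rm2 < {th['rm2_delta_max']}",
        t.rm2_avg,
        t.rm2_avg > th["rm2_avg_min"] and t.rm2_delta < th["rm2_delta_max"]))
    results.append(CriterionResult(
        "ccc", f"CCC > {th['ccc_min']}", t.ccc, t.ccc > th["ccc_min"]))
    return CriteriaReport(results)


def headline_threshold_checks(
    r2_train: float, q2_test: float, q2cv: float,
    r2_min: float = 0.6, q2_min: float = 0.5,
) -> dict[str, bool]:
    """Quick pass/fail on the headline correlation thresholds.

    Convenience for summarizing a model by its three headline numbers
    (training r2, external q2, cross-validated q2cv) against the standard
    acceptance thresholds r2 > 0.6 and q2 > 0.5.
    """
    return {
        "r2_train_gt_0.6": r2_train > r2_min,
        "q2_test_gt_0.5": q2_test > q2_min,
        "q2cv_gt_0.5": q2cv > q2_min,
    }


def pose_selection_confusion(selections, pose_table, group_cols, rmsd_col: str = "observed_rmsd") -> ConfusionMatrix:
    """Confusion matrix for qualitative top-pose selection.

    Within each candidate group a candidate is actual-positive if its
    observed RMSD equals the group minimum (ties: every tied candidate is
    actual-positive) and predicted-positive if it is the selected
    candidate.  ``selections`` holds one row per group carrying the full
    candidate key; ``group_cols`` defines the grouping.

    Raises if any group lacks a selection or any candidate lacks an
    observed RMSD.
    """
    import pandas as pd

    key_cols = [c for c in pose_table.columns
                if c in ("ligand_id", "structure_id", "conformer_id", "run_id", "pose_id")]
    df = pose_table.copy()
    if df[rmsd_col].isna().any():
        raise ValueError("observed RMSD required for every candidate")
    sel = selections[key_cols].copy()
    sel["_selected"] = True
    merged = df.merge(sel, on=key_cols, how="left")
    merged["_selected"] = merged["_selected"].notna() & merged["_selected"].eq(True)

    tp = fp = fn = tn = 0
    for _, grp in merged.groupby(group_cols, sort=False):
        if not grp["_selected"].any():
            raise ValueError(f"group without a selection: {grp[group_cols].iloc[0].tolist()}")
        actual = grp[rmsd_col] == grp[rmsd_col].min()
        predicted = grp["_selected"]
        tp += int((actual & predicted).sum())
        fp += int((~actual & predicted).sum())
        fn += int((actual & ~predicted).sum())
        tn += int((~actual & ~predicted).sum())
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def classification_report(cm: ConfusionMatrix) -> ClassificationReport:
    """Cooper statistics, MCC and Kubat's G-mean from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else 0.0
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else 0.0
    acc = (cm.tp + cm.tn) / cm.total
    denom = (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (cm.tp * cm.tn - cm.fp * cm.fn) / np.sqrt(denom)
    g_mean = float(np.sqrt(sens * spec))
    return ClassificationReport(
        sensitivity=sens, specificity=spec, accuracy=acc,
        mcc=float(mcc), g_mean=g_mean, mcc_degenerate=degenerate,
    )
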