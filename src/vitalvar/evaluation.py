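"""Performance measures, group statistics, and the interval/horizon sweeps.

Discrimination is summarised threshold-free by the area under the ROC curve
(trapezoidal over the empirical curve, equivalent to the Mann-Whitney
statistic with mid-ranks for ties) and the area under the precision-recall
curve; operating-point metrics (sensitivity, specificity, PPV, NPV,
accuracy) are reported at the 0.5 probability threshold.  Undefined
predictive values (empty denominator) are reported as NaN, never as 0.

``group_stats`` reproduces the septic-vs-control feature comparison: per
feature, group means and standard deviations with a two-sided Welch t-test
p-value.

The sweeps rerun the whole pipeline (simulate -> extract -> select -> train
-> evaluate) while varying either the data-collection interval T or the
prediction horizon, with per-value seeds derived deterministically from the
master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

from .features import featurize_cohort
from .models import FAMILIES, FitResult, classify, fit, stratified_split, tune
from .selection import select_features
from .synthetic import CohortSpec, GeneratorParams, simulate_cohort


@dataclass
class EvalReport:
    family: str
    n_test: int
    auc: float
    auc_pr: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int
    roc_points: np.ndarray = field(repr=False, default=None)  # columns FPR, TPR
    pr_points: np.ndarray = field(repr=False, default=None)  # columns recall, precision

    def as_dict(self) -> dict[str, float]:
        return {
            "family": self.family,
            "n_test": self.n_test,
            "auc": self.auc,
            "auc_pr": self.auc_pr,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def evaluate_scores(y_true: np.ndarray, scores: np.ndarray, *, family: str = "") -> EvalReport:
    """Full report from true labels and continuous scores/probabilities."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("evaluation requires both classes in the test set")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    precision, recall, _ = precision_recall_curve(y, s)
    # the convention here: precision at recall 0 equals the precision of the
    # most confident threshold rather than the appended value of 1
    precision = precision.copy()
    if precision.size >= 2:
        precision[-1] = precision[-2]
    auc_pr = float(-np.trapezoid(precision, recall))  # recall is decreasing
    calls = classify(s)
    tp = int(np.sum((calls == 1) & (y == 1)))
    fp = int(np.sum((calls == 1) & (y == 0)))
    tn = int(np.sum((calls == 0) & (y == 0)))
    fn = int(np.sum((calls == 0) & (y == 1)))
    return EvalReport(
        family=family,
        n_test=y.size,
        auc=auc,
        auc_pr=auc_pr,
        sensitivity=_safe_ratio(tp, tp + fn),
        specificity=_safe_ratio(tn, tn + fp),
        ppv=_safe_ratio(tp, tp + fp),
        npv=_safe_ratio(tn, tn + fn),
        accuracy=(tp + tn) / y.size,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        roc_points=np.column_stack((fpr, tpr)),
        pr_points=np.column_stack((recall, precision)),
    )


def evaluate(fit_result: FitResult, test: pd.DataFrame) -> EvalReport:
    """Evaluate a fitted model on a held-out feature table (with labels)."""
    probs = fit_result.predict_proba(test)
    return evaluate_scores(test["label"].to_numpy(), probs, family=fit_result.family)


# ---------------------------------------------------------------------------
# Group statistics (the population-separation table)


def group_stats(features: pd.DataFrame) -> pd.DataFrame:
    """Per-feature group means/SDs and two-sided Welch t-test p-values.

    Rows are feature names; columns septic_mean, septic_sd, control_mean,
    control_sd, p_value.  Requires at least two patients per group.
    """
    y = features["label"].to_numpy()
    septic = features[y == 1]
    control = features[y == 0]
    if len(septic) < 2 or len(control) < 2:
        raise ValueError("each group needs at least 2 patients for sd/p-value")
    rows = {}
    for col in features.columns:
        if col == "label":
            continue
        a, b = septic[col].to_numpy(), control[col].to_numpy()
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows[col] = {
            "septic_mean": float(a.mean()),
            "septic_sd": float(a.std(ddof=1)),
            "control_mean": float(b.mean()),
            "control_sd": float(b.std(ddof=1)),
            "p_value": p,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# End-to-end experiment and sweeps


@dataclass
class SweepResult:
    axis: str  # "collection_T" | "prediction_horizon"
    family: str
    table: pd.DataFrame  # columns: value (hours), auc, accuracy


def run_experiment(
    spec: CohortSpec,
    septic_params: GeneratorParams,
    control_params: GeneratorParams,
    family: str = "SVM_RBF",
    *,
    train_frac: float = 0.75,
    feature_set: str = "variability",
    select: bool = True,
    selection_families: Sequence[str] | None = None,
    n_repeats: int = 5,
    tune_model: bool = False,
    cv_folds: int = 10,
    seed: int = 0,
) -> EvalReport:
    """One full pipeline pass: simulate, extract, select, train, evaluate.

    Selection and tuning operate on the training rows only; the held-out
    test rows are touched once, by the final evaluation.
    """
    cohort = simulate_cohort(spec, septic_params, control_params)
    feats = featurize_cohort(cohort.series, spec.T_hours, spec.horizon_hours, feature_set)
    split = stratified_split(feats, train_frac, seed)
    train = feats.iloc[split.train_idx]
    test = feats.iloc[split.test_idx]
    if select:
        chosen = select_features(
            train, selection_families or (family,), k=2, n_repeats=n_repeats, seed=seed
        ).features
        train = train[["label"] + chosen]
        test = test[["label"] + chosen]
    hyper = None
    if tune_model:
        hyper = tune(family, train.drop(columns="label"), train["label"].to_numpy(), cv_folds=cv_folds, seed=seed)
    fitted = fit(family, train, train["label"].to_numpy(), hyper, seed=seed)
    return evaluate(fitted, test)


def _derived_seed(master: int, axis_code: int, value: float) -> int:
    ss = np.random.SeedSequence([int(master) % (2**31), axis_code, int(round(value * 1000))])
    return int(ss.generate_state(1)[0] % (2**31))


def sweep_collection_interval(
    spec: CohortSpec,
    septic_params: GeneratorParams,
    control_params: GeneratorParams,
    family: str = "SVM_RBF",
    T_values: Sequence[float] = (1, 2, 3, 4, 5, 6, 7, 8),
    seed: int = 0,
    **experiment_kwargs,
) -> SweepResult:
    """AUC as a function of the data-collection interval T (horizon fixed)."""
    rows = []
    for T in T_values:
        sub = replace(spec, T_hours=float(T), seed=_derived_seed(seed, 1, T))
        report = run_experiment(sub, septic_params, control_params, family, seed=sub.seed, **experiment_kwargs)
        rows.append({"value": float(T), "auc": report.auc, "accuracy": report.accuracy})
    return SweepResult(axis="collection_T", family=family, table=pd.DataFrame(rows))


def sweep_prediction_horizon(
    spec: CohortSpec,
    septic_params: GeneratorParams,
    control_params: GeneratorParams,
    family: str = "SVM_RBF",
    horizons: Sequence[float] = (1, 2, 3, 4, 5),
    seed: int = 0,
    **experiment_kwargs,
) -> SweepResult:
    """AUC as a function of the gap between the prediction moment and t0."""
    rows = []
    for h in horizons:
        sub = replace(spec, horizon_hours=float(h), seed=_derived_seed(seed, 2, h))
        report = run_experiment(sub, septic_params, control_params, family, seed=sub.seed, **experiment_kwargs)
        rows.append({"value": float(h), "auc": report.auc, "accuracy": report.accuracy})
    return SweepResult(axis="prediction_horizon", family=family, table=pd.DataFrame(rows))


def compare_feature_sets(
    cohort,
    families: Sequence[str] = FAMILIES,
    *,
    T_hours: float | None = None,
    horizon_hours: float | None = None,
    train_frac: float = 0.75,
    select: bool = True,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Variability vs descriptive features on the same windows and split.

    Both arms are featurised from the identical cohort, partitioned with the
    same seed (hence the same patients on each side), selected and trained
    independently; returns one row per (family, feature_set).
    """
    spec = cohort.spec
    T = spec.T_hours if T_hours is None else T_hours
    h = spec.horizon_hours if horizon_hours is None else horizon_hours
    rows = []
    for feature_set in ("variability", "baseline"):
        feats = featurize_cohort(cohort.series, T, h, feature_set)
        split = stratified_split(feats, train_frac, seed)
        train = feats.iloc[split.train_idx]
        test = feats.iloc[split.test_idx]
        for family in families:
            tr, te = train, test
            if select:
                chosen = select_features(tr, (family,), k=2, n_repeats=n_repeats, seed=seed).features
                tr = tr[["label"] + chosen]
                te = te[["label"] + chosen]
            fitted = fit(family, tr, tr["label"].to_numpy(), seed=seed)
            report = evaluate(fitted, te)
            rows.append({"family": family, "feature_set": feature_set, **{k: v for k, v in report.as_dict().items() if k != "family"}})
    return pd.DataFrame(rows)
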