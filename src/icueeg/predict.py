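"""Outcome classification: random forest, cross-validation, feature selection.

The classification problem is binary: poor outcome (dichotomized extended
Glasgow Outcome Scale 1-3) versus good (4-8).  Each patient contributes
three feature rows per timepoint (one per 10-min segment) as data
augmentation; to keep that augmentation leakage-free, cross-validation folds
are *grouped by patient* (all segments of a patient share a fold) and
stratified by outcome, and all reported metrics are computed at patient
level by averaging segment scores.

The forest is a 200-tree bagged ensemble; the out-of-bag (OOB) error as a
function of ensemble size is exposed for checking that 200 trees sit on the
error plateau.  Sensitivity/specificity use a Youden-optimal threshold
estimated from OOB scores on the training patients (never the test fold).
Backward feature elimination repeatedly drops the least-important feature
and tracks the cross-validated AUC; the chosen subset is the smallest one
whose AUC stays within a configurable drop (default 0.02) of the path
maximum.  Model comparison uses McNemar's test on paired correctness with
Benjamini-Hochberg false-discovery-rate correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedGroupKFold
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CVResult",
    "EliminationTrace",
    "aggregate_features",
    "attach_outcome",
    "train_random_forest",
    "oob_error_curve",
    "crossvalidate",
    "combined_model",
    "roc_metrics",
    "backward_elimination",
    "mcnemar_compare",
    "fdr_adjust",
    "impact_score",
    "load_impact_coefficients",
    "shuffle_patient_labels",
]


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def aggregate_features(features: pd.DataFrame, timepoints,
                       feature_cols: "list[str] | None" = None) -> pd.DataFrame:
    """Model matrix for one or several timepoints.

    For a single timepoint the segment rows are returned as-is.  For several
    (consecutive) timepoints the feature columns are concatenated across
    timepoints per (patient, segment), suffixed ``@<t>h``; patients missing
    a timepoint keep NaN entries there (imputed inside cross-validation from
    training folds).
    """
    timepoints = list(np.atleast_1d(timepoints).astype(float))
    if feature_cols is None:
        feature_cols = [c for c in features.columns
                        if c not in ("patient_id", "timepoint_h", "segment_id")]
    if len(timepoints) == 1:
        out = features[features["timepoint_h"] == timepoints[0]].copy()
        return out.drop(columns=["timepoint_h"]).reset_index(drop=True)
    merged: "pd.DataFrame | None" = None
    for tp in timepoints:
        sub = features[features["timepoint_h"] == tp]
        sub = sub.set_index(["patient_id", "segment_id"])[feature_cols]
        sub = sub.rename(columns={c: f"{c}@{tp:g}h" for c in feature_cols})
        merged = sub if merged is None else merged.join(sub, how="outer")
    return merged.reset_index()


def attach_outcome(matrix: pd.DataFrame, cohort_table: pd.DataFrame,
                   covariates: "list[str] | None" = None) -> pd.DataFrame:
    """Join outcome labels (and optionally IMPACT covariates) onto a model
    matrix by patient."""
    cols = ["patient_id", "outcome"] + list(covariates or [])
    return matrix.merge(cohort_table[cols], on="patient_id", how="left")


# ---------------------------------------------------------------------------
# forest training
# ---------------------------------------------------------------------------

def train_random_forest(X: np.ndarray, y: np.ndarray, n_trees: int = 200,
                        seed: int = 0) -> RandomForestClassifier:
    """Fit the bagged decision-tree ensemble with per-tree feature subsampling."""
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                 oob_score=True, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # OOB warnings on tiny fixtures
        clf.fit(X, y)
    return clf


def oob_error_curve(X: np.ndarray, y: np.ndarray, max_trees: int = 200,
                    step: int = 20, seed: int = 0) -> pd.DataFrame:
    """Out-of-bag error versus ensemble size (for choosing the tree count)."""
    clf = RandomForestClassifier(n_estimators=step, random_state=seed,
                                 oob_score=True, warm_start=True, n_jobs=1)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for n in range(step, max_trees + 1, step):
            clf.set_params(n_estimators=n)
            clf.fit(X, y)
            rows.append({"n_trees": n, "oob_error": 1.0 - clf.oob_score_})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Patient-level cross-validation metrics for one model."""

    fold_auc: np.ndarray
    fold_sensitivity: np.ndarray
    fold_specificity: np.ndarray
    patients: pd.DataFrame  # patient_id, outcome, score, pred, fold
    importances: pd.Series
    feature_names: list[str] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean(self.fold_auc))

    @property
    def predictions(self) -> pd.Series:
        """Hard per-patient predictions indexed by patient_id."""
        return self.patients.set_index("patient_id")["pred"]


def _impute_train_medians(train: np.ndarray, test: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    tr, te = train.copy(), test.copy()
    for arr in (tr, te):
        nan = np.isnan(arr)
        arr[nan] = np.take(med, np.nonzero(nan)[1])
    return tr, te


def _youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Youden-optimal cut, placed midway between the adjacent score levels
    so it does not sit exactly on a training score (more robust when the
    test-score distribution is shifted slightly)."""
    if len(np.unique(labels)) < 2:
        return 0.5
    fpr, tpr, thr = roc_curve(labels, scores)
    best = float(thr[np.argmax(tpr - fpr)])
    below = scores[scores < best]
    if below.size == 0:
        return best
    return (best + float(below.max())) / 2.0


def crossvalidate(table: pd.DataFrame, feature_cols: list[str], k: int = 5,
                  seed: int = 0, n_trees: int = 200) -> CVResult:
    """Grouped, stratified k-fold cross-validation of the random forest.

    ``table`` needs ``patient_id``, ``outcome`` and the feature columns; one
    row per segment.  Missing values are imputed with training-fold medians.
    Folds with a single outcome class in the test patients yield NaN AUC and
    a warning.
    """
    y = table["outcome"].to_numpy(int)
    groups = table["patient_id"].to_numpy()
    X = table[feature_cols].to_numpy(float)
    if min(np.bincount(table.drop_duplicates("patient_id")["outcome"])) < 2:
        raise ValueError("need at least 2 patients per outcome class")

    cv = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_auc, fold_sens, fold_spec = [], [], []
    pat_rows, importances = [], []
    for fold, (tr, te) in enumerate(cv.split(X, y, groups)):
        Xtr, Xte = _impute_train_medians(X[tr], X[te])
        clf = train_random_forest(Xtr, y[tr], n_trees=n_trees, seed=seed + fold)
        importances.append(clf.feature_importances_)

        # Youden threshold from OOB scores of the *training* patients
        oob = clf.oob_decision_function_[:, -1]
        tr_pat = pd.DataFrame({"pid": groups[tr], "y": y[tr], "s": oob})
        tr_agg = tr_pat.groupby("pid").agg(y=("y", "first"), s=("s", "mean")).dropna()
        threshold = _youden_threshold(tr_agg["s"].to_numpy(), tr_agg["y"].to_numpy())

        prob = clf.predict_proba(Xte)[:, list(clf.classes_).index(1)] \
            if 1 in clf.classes_ else np.zeros(len(te))
        te_pat = pd.DataFrame({"pid": groups[te], "y": y[te], "s": prob})
        agg = te_pat.groupby("pid").agg(y=("y", "first"), s=("s", "mean"))
        yy, ss = agg["y"].to_numpy(), agg["s"].to_numpy()
        pred = (ss >= threshold).astype(int)
        if len(np.unique(yy)) < 2:
            warnings.warn(f"fold {fold}: single outcome class, AUC undefined")
            fold_auc.append(np.nan)
        else:
            fold_auc.append(roc_auc_score(yy, ss))
        tp = int(((pred == 1) & (yy == 1)).sum())
        fn = int(((pred == 0) & (yy == 1)).sum())
        tn = int(((pred == 0) & (yy == 0)).sum())
        fp = int(((pred == 1) & (yy == 0)).sum())
        fold_sens.append(tp / (tp + fn) if tp + fn else np.nan)
        fold_spec.append(tn / (tn + fp) if tn + fp else np.nan)
        for pid, yv, sv, pv in zip(agg.index, yy, ss, pred):
            pat_rows.append({"patient_id": pid, "outcome": int(yv),
                             "score": float(sv), "pred": int(pv), "fold": fold})

    return CVResult(
        fold_auc=np.array(fold_auc), fold_sensitivity=np.array(fold_sens),
        fold_specificity=np.array(fold_spec),
        patients=pd.DataFrame(pat_rows),
        importances=pd.Series(np.mean(importances, axis=0), index=feature_cols),
        feature_names=list(feature_cols),
    )


def roc_metrics(scores: np.ndarray, labels: np.ndarray,
                threshold: "float | None" = None
                ) -> tuple[float, float, float, pd.DataFrame]:
    """AUC, sensitivity and specificity of per-patient scores.

    AUC is the trapezoidal area under the ROC curve (ties counted 1/2).
    Poor outcome (label 1) is the positive class.  If no threshold is given
    the Youden-optimal point of these scores is used.
    """
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    if threshold is None:
        threshold = _youden_threshold(scores, labels)
    pred = scores >= threshold
    sens = float((pred & (labels == 1)).sum() / max((labels == 1).sum(), 1))
    spec = float((~pred & (labels == 0)).sum() / max((labels == 0).sum(), 1))
    return auc, sens, spec, points


# ---------------------------------------------------------------------------
# backward feature elimination
# ---------------------------------------------------------------------------

@dataclass
class EliminationTrace:
    """Backward-elimination path and the chosen feature subset."""

    steps: pd.DataFrame  # n_features, auc, removed (feature dropped after the step)
    subsets: list[list[str]]  # feature set evaluated at each step
    chosen: list[str]

    @property
    def best_auc(self) -> float:
        return float(self.steps["auc"].max())


def backward_elimination(table: pd.DataFrame, feature_cols: list[str], k: int = 5,
                         seed: int = 0, n_trees: int = 200,
                         drop_tol: float = 0.02) -> EliminationTrace:
    """Iteratively drop the least-important feature, tracking the CV AUC.

    At each step the model is cross-validated on the current feature set and
    the feature with the lowest mean importance is removed (ties broken by
    dropping the lexicographically last name).  The chosen subset is the
    smallest one whose AUC is within ``drop_tol`` of the path maximum,
    operationalizing the "substantial drop" stop rule.
    """
    current = list(feature_cols)
    rows, subsets = [], []
    while current:
        res = crossvalidate(table, current, k=k, seed=seed, n_trees=n_trees)
        subsets.append(list(current))
        if len(current) == 1:
            rows.append({"n_features": 1, "auc": res.mean_auc, "removed": ""})
            break
        imp = res.importances
        worst = imp[imp == imp.min()].index.max()  # lexicographically last on ties
        rows.append({"n_features": len(current), "auc": res.mean_auc,
                     "removed": worst})
        current.remove(worst)
    steps = pd.DataFrame(rows)
    target = steps["auc"].max() - drop_tol
    eligible = steps.index[steps["auc"] >= target]
    pick = int(eligible[-1])  # latest step = fewest features
    return EliminationTrace(steps=steps, subsets=subsets, chosen=subsets[pick])


# ---------------------------------------------------------------------------
# model comparison & baseline
# ---------------------------------------------------------------------------

def mcnemar_compare(preds_a, preds_b, labels, exact_below: int = 25
                    ) -> tuple[float, float]:
    """McNemar's paired test on prediction correctness.

    Builds the 2x2 discordance table of (A correct, B correct); the exact
    binomial version is used when fewer than ``exact_below`` discordant
    pairs exist, otherwise the chi-square version with continuity
    correction.  Returns (statistic, p).  Identical predictions give p = 1.
    """
    a = np.asarray(preds_a, int) == np.asarray(labels, int)
    b = np.asarray(preds_b, int) == np.asarray(labels, int)
    n11 = int((a & b).sum())
    n10 = int((a & ~b).sum())
    n01 = int((~a & b).sum())
    n00 = int((~a & ~b).sum())
    if n10 + n01 == 0:
        return 0.0, 1.0
    exact = (n10 + n01) < exact_below
    res = _sm_mcnemar([[n11, n10], [n01, n00]], exact=exact, correction=True)
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def load_impact_coefficients(path: "str | None" = None) -> dict:
    """Read an IMPACT logistic-model coefficient mapping from YAML
    (``intercept`` plus one entry per covariate).

    Without a path, the bundled *synthetic* coefficient set is loaded — it
    matches the synthetic cohort's covariates and is meant for examples and
    tests, not for real prognostication.
    """
    import yaml

    if path is None:
        from importlib import resources

        path = resources.files("icueeg") / "config" / "impact_synthetic.yaml"
    with open(str(path)) as fh:
        coef = yaml.safe_load(fh)
    if "intercept" not in coef:
        raise KeyError("coefficient config must define 'intercept'")
    return coef


def impact_score(covariates: pd.DataFrame, coefficients: dict) -> np.ndarray:
    """Probability of poor outcome from the IMPACT logistic model.

    ``coefficients`` maps covariate names to log-odds weights plus an
    ``intercept``; each named covariate must be present in ``covariates``
    (a missing one raises a KeyError naming the field).  Coefficient values
    are supplied by configuration, not hard-coded.
    """
    lin = np.full(len(covariates), float(coefficients["intercept"]))
    for name, beta in coefficients.items():
        if name == "intercept":
            continue
        if name not in covariates.columns:
            raise KeyError(f"missing IMPACT covariate: {name!r}")
        lin += float(beta) * covariates[name].to_numpy(float)
    return 1.0 / (1.0 + np.exp(-lin))


def combined_model(table: pd.DataFrame, eeg_features: list[str],
                   covariates: list[str], k: int = 5, seed: int = 0,
                   n_trees: int = 200) -> CVResult:
    """Random forest on the union of selected EEG features and IMPACT
    covariates, under the same grouped CV protocol; the feature-importance
    ranking (EEG vs clinical provenance) is available via
    :func:`icueeg.report.importance_report`."""
    return crossvalidate(table, list(eeg_features) + list(covariates), k=k,
                         seed=seed, n_trees=n_trees)


def shuffle_patient_labels(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Permute outcome labels at patient level (null-model probe)."""
    rng = np.random.default_rng(seed)
    pats = table.drop_duplicates("patient_id")[["patient_id", "outcome"]]
    perm = rng.permutation(pats["outcome"].to_numpy())
    mapping = dict(zip(pats["patient_id"], perm))
    out = table.copy()
    out["outcome"] = out["patient_id"].map(mapping)
    return out
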