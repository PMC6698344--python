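"""Voxel-wise amyloid-positivity classifier with nested cross-validation.

The classification task: given a subject's annualized volumetric-change
map, predict whether the subject is amyloid positive (PreAD) or negative
(Ctrl).  The estimator is ridge (L2) logistic regression on a small
fraction of voxels picked by a univariate F-test filter; performance is
estimated by a repeated, prevalence-fixed nested cross-validation:

- outer loop: subjects are split 80/20 into development and test sets,
  with the test set forced to a target positive-class prevalence (20% by
  default, a realistic amyloid-positivity rate in middle-aged adults);
  splitting is by subject, so no subject contributes maps to both sides;
- inner loop: k-fold (k = 3) grid search over the ridge strength C,
  maximizing validation F1;
- the whole procedure is repeated n times (100 by default) and metrics
  are summarized by mean, s.d. and intervals across repeats.

Evaluation can additionally be restricted to scan pairs with long
intervals (dt windows), which is where the preclinical signal rises above
the per-scan noise floor.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

__all__ = [
    "FeatureMatrix",
    "SelectionMask",
    "NestedCVConfig",
    "PerfMetrics",
    "CVResult",
    "build_feature_matrix",
    "rank_features_ftest",
    "select_fraction",
    "make_prevalence_split",
    "tune_ridge_C",
    "fit_ridge_logistic",
    "RidgeLogisticModel",
    "compute_metrics",
    "run_nested_cv",
    "evaluate_vs_dt",
    "selection_frequency_map",
]

POSITIVE_GROUP = "PreAD"


# ---------------------------------------------------------------------------
# Containers

@dataclass
class FeatureMatrix:
    """Flattened within-mask voxel features, one row per annualized map."""

    X: np.ndarray                 # (n_maps, n_voxels)
    meta: pd.DataFrame            # subject_id, group, label, dt, mean_age
    mask: np.ndarray              # 3-D bool analysis mask (column geometry)

    def __post_init__(self) -> None:
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("metadata rows must match X rows")
        if int(self.mask.sum()) != self.X.shape[1]:
            raise ValueError("mask voxel count must match X columns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def y(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    @property
    def subjects(self) -> np.ndarray:
        return self.meta["subject_id"].to_numpy()

    def subject_labels(self) -> pd.Series:
        """Per-subject class label (constant across a subject's maps)."""
        return self.meta.groupby("subject_id")["label"].first()


@dataclass
class SelectionMask:
    """F-test ranking of feature columns and the selected top fraction."""

    ranked_voxel_indices: np.ndarray   # descending score, ties by ascending index
    scores: np.ndarray                 # per-column F statistics
    selected_fraction: float
    selected_indices: np.ndarray       # the kept columns, ranking order

    def __post_init__(self) -> None:
        if len(np.unique(self.ranked_voxel_indices)) != len(self.ranked_voxel_indices):
            raise ValueError("ranked indices must be unique")
        if len(self.selected_indices) < 1:
            raise ValueError("at least one feature must be selected")


@dataclass
class NestedCVConfig:
    """Knobs of the repeated prevalence-fixed nested cross-validation."""

    outer_test_fraction: float = 0.20
    test_prevalence: float = 0.20
    inner_folds: int = 3
    C_grid: tuple[float, ...] = tuple(np.logspace(-3, 3, 13))
    n_repeats: int = 100
    seed: int = 0
    feature_fraction: float = 0.005
    selection_method: str = "f_test"      # or "l1_embedded"
    l1_C: float = 1.0
    residualize_age: bool = False
    dt_train_window: Optional[tuple[float, float]] = None
    dt_eval_window: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not 0 < self.outer_test_fraction < 1:
            raise ValueError("outer_test_fraction must be in (0, 1)")
        if not 0 < self.test_prevalence < 1:
            raise ValueError("test_prevalence must be in (0, 1)")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if len(self.C_grid) == 0:
            raise ValueError("C_grid must be nonempty")
        if self.selection_method not in ("f_test", "l1_embedded"):
            raise ValueError(f"unknown selection_method {self.selection_method!r}")


@dataclass(frozen=True)
class PerfMetrics:
    auc: float
    accuracy: float
    balanced_accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not (0.0 <= v <= 1.0 or math.isnan(v)):
                raise ValueError(f"{name} out of [0, 1]: {v}")
        expected = 0.5 * (self.sensitivity + self.specificity)
        if abs(self.balanced_accuracy - expected) > 1e-9:
            raise ValueError("balanced_accuracy must equal (sensitivity+specificity)/2")

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
        }


METRIC_NAMES = ("auc", "accuracy", "balanced_accuracy", "precision", "sensitivity", "specificity", "f1")


@dataclass
class CVResult:
    """Aggregated outcome of the repeated nested cross-validation."""

    metrics: pd.DataFrame            # one row per (valid) repeat
    chosen_C: list[float]
    selections: list[SelectionMask]
    scores: pd.DataFrame             # per test map: repeat, subject_id, dt, y, score
    weight_checksums: list[str]      # train-time artifact fingerprints per repeat
    config: NestedCVConfig
    n_repeats_requested: int
    n_repeats_valid: int

    def summary(self, interval: str = "percentile") -> pd.DataFrame:
        """Mean, s.d. and interval per metric across repeats.

        ``interval``: ``percentile`` (2.5/97.5 across repeats, default) or
        ``minmax`` (extreme range).
        """
        rows = {}
        for m in METRIC_NAMES:
            v = self.metrics[m].to_numpy()
            if interval == "percentile":
                lo, hi = np.percentile(v, [2.5, 97.5])
            elif interval == "minmax":
                lo, hi = v.min(), v.max()
            else:
                raise ValueError(f"unknown interval type {interval!r}")
            rows[m] = {"mean": v.mean(), "sd": v.std(ddof=1) if len(v) > 1 else 0.0, "lo": lo, "hi": hi}
        return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Feature matrix construction

def build_feature_matrix(
    dataset,
    mask: Optional[np.ndarray] = None,
    groups: Sequence[str] = ("Ctrl", "PreAD"),
    positive_group: str = POSITIVE_GROUP,
) -> FeatureMatrix:
    """Annualize the dataset's change maps and flatten them within a mask.

    Maps are converted to annual log-volume-change rates (log J / dt) and
    the voxels inside ``mask`` (default: the whole simulated brain) become
    feature columns, identically ordered for every row.
    """
    atlas = dataset.atlas
    mask = atlas.brain_mask if mask is None else np.asarray(mask, dtype=bool)
    rows, meta = [], []
    for pair, group, jmap in zip(dataset.pairs, dataset.pair_groups, dataset.maps):
        gname = group.value if hasattr(group, "value") else str(group)
        if gname not in groups:
            continue
        if jmap.scale == "log_det":
            annual = jmap.values / pair.dt
        elif jmap.scale == "annualized_log_det":
            annual = jmap.values
        elif jmap.scale == "raw_det":
            annual = np.log(jmap.values) / pair.dt
        else:
            raise ValueError(f"unsupported map scale {jmap.scale!r}")
        rows.append(annual[mask])
        meta.append(
            {
                "subject_id": pair.subject_id,
                "group": gname,
                "label": int(gname == positive_group),
                "dt": pair.dt,
                "mean_age": pair.mean_age,
            }
        )
    if not rows:
        raise ValueError("no maps matched the requested groups")
    return FeatureMatrix(X=np.asarray(rows, dtype=float), meta=pd.DataFrame(meta), mask=mask)


# ---------------------------------------------------------------------------
# Feature selection

def rank_features_ftest(X: np.ndarray, y: np.ndarray) -> SelectionMask:
    """Rank columns by the one-way ANOVA F statistic between the classes.

    For two classes F equals the square of the pooled-variance two-sample
    t statistic.  Ties (including zero-variance columns, whose F is set
    to 0) are broken by ascending column index, so the ranking is
    deterministic.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # constant columns emit runtime warnings
        F, _ = f_classif(X, y)
    F = np.nan_to_num(F, nan=0.0, posinf=np.finfo(float).max)
    order = np.argsort(-F, kind="stable")
    return SelectionMask(
        ranked_voxel_indices=order,
        scores=F,
        selected_fraction=1.0,
        selected_indices=order,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def select_fraction(mask: SelectionMask, fraction: float) -> SelectionMask:
    """Keep the top ``round(fraction * n_columns)`` ranked columns (min 1)."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(mask.scores)
    n_sel = max(1, _round_half_up(fraction * n))
    return replace(
        mask,
        selected_fraction=fraction,
        selected_indices=mask.ranked_voxel_indices[:n_sel],
    )


def n_selected_features(n_columns: int, fraction: float) -> int:
    """Number of features kept at a given fraction (round half up, min 1)."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return max(1, _round_half_up(fraction * n_columns))


# ---------------------------------------------------------------------------
# Prevalence-fixed subject split

def make_prevalence_split(
    subject_ids: Sequence[str],
    subject_labels: Sequence[int],
    test_fraction: float,
    rho: float,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Split subjects into train/test with the test prevalence forced to rho.

    The test set holds ``round(test_fraction * N)`` subjects of which
    ``round(rho * test_size)`` are positive; classes are sampled without
    replacement (stratified draw, down-sampling whichever class is
    over-represented relative to rho).  All remaining subjects train.
    """
    ids = np.asarray(subject_ids)
    labels = np.asarray(subject_labels)
    if len(ids) != len(labels):
        raise ValueError("one label per subject required")
    n = len(ids)
    n_test = _round_half_up(test_fraction * n)
    n_pos_test = _round_half_up(rho * n_test)
    n_neg_test = n_test - n_pos_test
    pos = ids[labels == 1]
    neg = ids[labels == 0]
    lo = max(0, n_test - len(neg))
    hi = min(len(pos), n_test)
    if not (lo <= n_pos_test <= hi) or n_pos_test < 1 or n_neg_test < 1:
        attainable = (max(lo, 1) / n_test, min(hi, n_test - 1) / n_test) if n_test >= 2 else (np.nan, np.nan)
        raise ValueError(
            f"test prevalence {rho} unattainable with {len(pos)} positives / "
            f"{len(neg)} negatives and test size {n_test}; attainable prevalence "
            f"range is [{attainable[0]:.3f}, {attainable[1]:.3f}]"
        )
    test_pos = rng.choice(pos, size=n_pos_test, replace=False)
    test_neg = rng.choice(neg, size=n_neg_test, replace=False)
    test = set(test_pos) | set(test_neg)
    train = [s for s in ids if s not in test]
    train_labels = labels[np.isin(ids, train)]
    if len(np.unique(train_labels)) < 2:
        raise ValueError("split leaves the training set with a single class")
    return train, sorted(test)


# ---------------------------------------------------------------------------
# Ridge logistic regression

class RidgeLogisticModel:
    """L2-penalized logistic regression with train-set standardization.

    Minimizes the sum of logistic losses plus ||w||² / (2C); the intercept
    is unpenalized.  Features are z-scored with the training statistics
    (zero-variance columns get unit scale) before fitting and scoring.
    """

    def __init__(self, C: float, tol: float = 1e-6, max_iter: int = 5000):
        self.C = C
        self.tol = tol
        self.max_iter = max_iter
        self.mean_: Optional[np.ndarray] = None
        self.scale_: Optional[np.ndarray] = None
        self.clf_: Optional[LogisticRegression] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RidgeLogisticModel":
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite features")
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes to fit")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        Z = (X - self.mean_) / self.scale_
        # default penalty is the L2 ridge; objective = sum losses + ||w||^2/(2C)
        self.clf_ = LogisticRegression(
            C=self.C, solver="lbfgs", tol=self.tol, max_iter=self.max_iter
        )
        self.clf_.fit(Z, y)
        return self

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(positive class) per row."""
        return self.clf_.predict_proba(self._transform(X))[:, 1]

    @property
    def weights(self) -> np.ndarray:
        return self.clf_.coef_.ravel()

    @property
    def intercept(self) -> float:
        return float(self.clf_.intercept_[0])


def fit_ridge_logistic(X: np.ndarray, y: np.ndarray, C: float) -> RidgeLogisticModel:
    return RidgeLogisticModel(C=C).fit(X, y)


def _stratified_subject_folds(
    subjects: np.ndarray, labels_by_subject: dict, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Assign subjects to k folds, stratified by subject class label."""
    uniq = np.unique(subjects)
    folds = [[] for _ in range(k)]
    for cls in (0, 1):
        members = np.array([s for s in uniq if labels_by_subject[s] == cls])
        members = members[rng.permutation(len(members))]
        for i, s in enumerate(members):
            folds[i % k].append(s)
    return [np.array(f) for f in folds]


def tune_ridge_C(
    X: np.ndarray,
    y: np.ndarray,
    subjects: Sequence[str],
    C_grid: Sequence[float],
    k: int = 3,
    rng: Optional[np.random.Generator] = None,
    max_redraws: int = 20,
) -> float:
    """Inner-loop grid search: best C by mean validation F1 over k subject folds.

    Folds are split by subject and stratified by class; if a fold still
    loses a class (possible with very few subjects), folds are redrawn.
    Ties go to the smallest C (strongest regularization).
    """
    if len(C_grid) == 0:
        raise ValueError("empty C grid")
    if len(C_grid) == 1:
        return float(C_grid[0])
    rng = rng or np.random.default_rng(0)
    subjects = np.asarray(subjects)
    labels_by_subject = dict(pd.DataFrame({"s": subjects, "y": y}).groupby("s")["y"].first())

    folds = None
    for _ in range(max_redraws):
        cand = _stratified_subject_folds(subjects, labels_by_subject, k, rng)
        ok = True
        for f in cand:
            val = np.isin(subjects, f)
            if len(np.unique(y[val])) < 2 or len(np.unique(y[~val])) < 2:
                ok = False
                break
        if ok:
            folds = cand
            break
    if folds is None:
        raise ValueError("cannot build class-stratified subject folds")

    mean_f1 = np.zeros(len(C_grid))
    for f in folds:
        val = np.isin(subjects, f)
        for ci, C in enumerate(C_grid):
            model = fit_ridge_logistic(X[~val], y[~val], C)
            pred = (model.predict_proba(X[val]) >= 0.5).astype(int)
            tp = int(np.sum((pred == 1) & (y[val] == 1)))
            fp = int(np.sum((pred == 1) & (y[val] == 0)))
            fn = int(np.sum((pred == 0) & (y[val] == 1)))
            f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
            mean_f1[ci] += f1 / len(folds)
    best = np.max(mean_f1)
    # ties -> smallest C among (near-)maximal scores
    candidates = [C for C, s in zip(C_grid, mean_f1) if s >= best - 1e-12]
    return float(min(candidates))


# ---------------------------------------------------------------------------
# Metrics

def compute_metrics(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> PerfMetrics:
    """Standard binary performance metrics from continuous scores.

    AUC uses the rank statistic (midranks on ties); the confusion-matrix
    metrics threshold the scores at ``threshold``.  Precision with zero
    predicted positives is defined as 0 (with a warning).
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: y_true contains a single class")
    auc = float(roc_auc_score(y, s))
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision defined as 0", RuntimeWarning)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    accuracy = (tp + tn) / len(y)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return PerfMetrics(
        auc=auc,
        accuracy=accuracy,
        balanced_accuracy=0.5 * (sensitivity + specificity),
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
    )


# ---------------------------------------------------------------------------
# Nested CV

def _in_window(dt: np.ndarray, window: Optional[tuple[float, float]]) -> np.ndarray:
    if window is None:
        return np.ones(len(dt), dtype=bool)
    lo, hi = window
    return (dt > lo) & (dt < hi)


def _residualize_on_train_controls(
    X: np.ndarray, meta: pd.DataFrame, train_rows: np.ndarray
) -> np.ndarray:
    """Regress out age column-wise, coefficients fitted on train controls only."""
    ctrl = train_rows & (meta["label"].to_numpy() == 0)
    ages = meta["mean_age"].to_numpy()
    if ctrl.sum() < 3 or np.ptp(ages[ctrl]) == 0:
        raise ValueError("cannot fit age model: too few train controls or constant age")
    a0 = ages[ctrl].mean()
    ac = ages[ctrl] - a0
    slope = ac @ (X[ctrl] - X[ctrl].mean(axis=0)) / np.sum(ac**2)
    return X - np.outer(ages - a0, slope)


def _repeat_rng(seed: int, repeat: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2, repeat)))


def run_nested_cv(fm: FeatureMatrix, cfg: NestedCVConfig) -> CVResult:
    """Run the full repeated prevalence-fixed nested cross-validation.

    Per repeat: prevalence-fixed outer split by subject -> (optional) age
    residualization and feature ranking on the training maps only ->
    fixed-fraction selection -> inner C grid search -> ridge fit on the
    whole training set -> metrics on the held-out maps.  Repeats whose
    dt-restricted test set has fewer than two maps in either class are
    flagged invalid and excluded from the aggregate.
    """
    subj_labels = fm.subject_labels()
    subject_ids = subj_labels.index.to_numpy()
    labels = subj_labels.to_numpy()
    dt = fm.meta["dt"].to_numpy()

    rows_metrics, chosen_C, selections, score_rows, checksums = [], [], [], [], []
    n_valid = 0
    for rep in range(cfg.n_repeats):
        rng = _repeat_rng(cfg.seed, rep)
        train_ids, test_ids = make_prevalence_split(
            subject_ids, labels, cfg.outer_test_fraction, cfg.test_prevalence, rng
        )
        in_train = np.isin(fm.subjects, train_ids) & _in_window(dt, cfg.dt_train_window)
        in_test = np.isin(fm.subjects, test_ids) & _in_window(dt, cfg.dt_eval_window)

        y_test = fm.y[in_test]
        if np.sum(y_test == 1) < 2 or np.sum(y_test == 0) < 2:
            continue  # flagged missing for this repeat
        X = fm.X
        if cfg.residualize_age:
            X = _residualize_on_train_controls(X, fm.meta, in_train)

        X_train, y_train = X[in_train], fm.y[in_train]
        subj_train = fm.subjects[in_train]

        if cfg.selection_method == "f_test":
            ranking = rank_features_ftest(X_train, y_train)
            sel = select_fraction(ranking, cfg.feature_fraction)
        else:  # l1_embedded
            probe = RidgeLogisticModel(C=cfg.l1_C)
            probe.mean_ = X_train.mean(axis=0)
            sd = X_train.std(axis=0)
            sd[sd == 0] = 1.0
            probe.scale_ = sd
            Z = (X_train - probe.mean_) / probe.scale_
            lasso = LogisticRegression(l1_ratio=1, C=cfg.l1_C, solver="liblinear", max_iter=2000)
            lasso.fit(Z, y_train)
            coef = lasso.coef_.ravel()
            nz = np.flatnonzero(coef != 0)
            if len(nz) == 0:
                nz = np.array([int(np.argmax(np.abs(coef)))])
            order = nz[np.argsort(-np.abs(coef[nz]), kind="stable")]
            rest = np.setdiff1d(np.arange(X.shape[1]), order, assume_unique=False)
            sel = SelectionMask(
                ranked_voxel_indices=np.concatenate([order, rest]),
                scores=np.abs(coef),
                selected_fraction=len(order) / X.shape[1],
                selected_indices=order,
            )

        cols = sel.selected_indices
        best_C = tune_ridge_C(
            X_train[:, cols], y_train, subj_train, cfg.C_grid, k=cfg.inner_folds, rng=rng
        )
        model = fit_ridge_logistic(X_train[:, cols], y_train, best_C)
        checksums.append(
            hashlib.sha256(
                np.round(model.weights, 12).tobytes()
                + np.asarray(cols).tobytes()
                + np.float64(best_C).tobytes()
            ).hexdigest()
        )

        scores = model.predict_proba(X[in_test][:, cols])
        m = compute_metrics(y_test, scores)
        rows_metrics.append({"repeat": rep, **m.as_dict()})
        chosen_C.append(best_C)
        selections.append(sel)
        for sid, d, yt, sc in zip(
            fm.subjects[in_test], dt[in_test], y_test, scores
        ):
            score_rows.append(
                {"repeat": rep, "subject_id": sid, "dt": d, "y": int(yt), "score": float(sc)}
            )
        n_valid += 1

    if n_valid == 0:
        raise ValueError("no repeat produced a valid (two-class) test set")
    return CVResult(
        metrics=pd.DataFrame(rows_metrics),
        chosen_C=chosen_C,
        selections=selections,
        scores=pd.DataFrame(score_rows),
        weight_checksums=checksums,
        config=cfg,
        n_repeats_requested=cfg.n_repeats,
        n_repeats_valid=n_valid,
    )


def evaluate_vs_dt(
    fm: FeatureMatrix,
    cfg: NestedCVConfig,
    dt_thresholds: Sequence[float],
    savings_params=None,
) -> pd.DataFrame:
    """Classifier performance as a function of the minimal test-set dt.

    For each threshold theta the nested CV is re-run with the test maps
    restricted to dt > theta (training maps unrestricted unless
    ``cfg.dt_train_window`` is set).  Returns one row per threshold with
    mean metrics, the triage savings at the mean operating point, and the
    number of valid repeats; thresholds where no repeat retains two maps
    per class are flagged missing (NaN metrics).
    """
    from .savings import SavingsParams, savings_cost, savings_tests

    if list(dt_thresholds) != sorted(dt_thresholds):
        raise ValueError("thresholds must be sorted ascending")
    params = savings_params or SavingsParams(rho=cfg.test_prevalence)
    rows = []
    for theta in dt_thresholds:
        sub = replace(cfg, dt_eval_window=(theta, math.inf))
        try:
            res = run_nested_cv(fm, sub)
        except ValueError:
            rows.append({"dt_threshold": theta, "n_valid_repeats": 0, "missing": True})
            continue
        summ = res.summary()
        P, R = summ.loc["precision", "mean"], summ.loc["sensitivity", "mean"]
        row = {
            "dt_threshold": theta,
            "n_valid_repeats": res.n_repeats_valid,
            "missing": False,
        }
        for m in METRIC_NAMES:
            row[f"mean_{m}"] = summ.loc[m, "mean"]
        row["savings_cost"] = savings_cost(P, R, params) if P > 0 and R > 0 else float("nan")
        row["savings_tests"] = savings_tests(P, params.rho) if P > 0 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def selection_frequency_map(result: CVResult, mask: np.ndarray) -> np.ndarray:
    """Per-voxel selection frequency across repeats, on the mask geometry.

    Returns a 3-D volume where each within-mask voxel holds the fraction
    of repeats in which it was selected (0..1); voxels outside the mask
    are 0.
    """
    mask = np.asarray(mask, dtype=bool)
    n_cols = len(result.selections[0].scores)
    if int(mask.sum()) != n_cols:
        raise ValueError(
            f"geometry mismatch: mask has {int(mask.sum())} voxels, "
            f"selections cover {n_cols} columns"
        )
    counts = np.zeros(n_cols)
    for sel in result.selections:
        counts[sel.selected_indices] += 1
    freq = counts / len(result.selections)
    vol = np.zeros(mask.shape)
    vol[mask] = freq
    return vol
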