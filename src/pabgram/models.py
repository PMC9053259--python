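"""Per-selection susceptibility classifiers and the model-selection procedure.

For each antibiotic selection a binary classifier estimates the probability
that the selection covers the infection, from the sparse bag-of-words
features. The search space spans four model classes — L1 (lasso) and L2
(ridge) logistic regression, random forests, and gradient-boosted trees —
chosen for their spread of bias/variance. The procedure:

1. per class, stratified 5-fold cross-validated grid search on the
   training years, scored by mean AUROC;
2. refit each class's best configuration on the full training set and
   score it on the validation year; the class with the highest validation
   AUROC wins (ties broken by the fixed order L1 > L2 > RF > GBT);
3. re-tune the winning class on train+validation with the same CV grid
   search, then fit the final model on train+validation.

Gradient-boosted trees additionally hold out 5% of whatever data they are
fit on as an early-stopping set (max 1000 boosting rounds, patience 10,
validation log-loss). Training data are never re-weighted or re-sampled,
preserving calibration. Test metrics (AUROC, average precision) carry 95%
percentile bootstrap confidence intervals over 1000 test resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold, train_test_split

#: tie-break order for class selection (simplest first)
CLASS_ORDER = ("l1", "l2", "rf", "gbt")

# lightgbm names columns of sparse training matrices internally; the
# resulting sklearn feature-name check at predict time is spurious here
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names", category=UserWarning
)


def default_grids() -> dict[str, dict[str, list]]:
    return {
        "l1": {"C": list(np.logspace(-3, 2, 7))},
        "l2": {"C": list(np.logspace(-3, 2, 7))},
        "rf": {
            "n_estimators": [200, 500],
            "max_depth": [None, 10, 20],
            "min_samples_leaf": [1, 5],
        },
        "gbt": {
            "learning_rate": [0.03, 0.1],
            "num_leaves": [15, 31],
            "min_child_samples": [10, 50],
        },
    }


def desk_grids() -> dict[str, dict[str, list]]:
    """Reduced grids for desk-scale end-to-end runs."""
    return {
        "l1": {"C": [0.1, 1.0]},
        "l2": {"C": [0.1, 1.0]},
        "rf": {"n_estimators": [150], "max_depth": [10, None], "min_samples_leaf": [5]},
        "gbt": {"learning_rate": [0.1], "num_leaves": [15, 31], "min_child_samples": [20]},
    }


@dataclass
class ModelSelectionPlan:
    """Temporal splits and search configuration for the model suite."""

    train_years: tuple[int, int] = (2009, 2017)  # inclusive
    validation_years: tuple[int, int] = (2018, 2018)
    test_years: tuple[int, int] = (2019, 2019)
    model_classes: tuple[str, ...] = CLASS_ORDER
    grids: dict[str, dict[str, list]] = field(default_factory=default_grids)
    cv_folds: int = 5
    early_stopping_holdout: float = 0.05
    max_boosting_rounds: int = 1000
    early_stopping_patience: int = 10
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        spans = [self.train_years, self.validation_years, self.test_years]
        for lo, hi in spans:
            if lo > hi:
                raise ValueError(f"year span {lo}-{hi} is inverted")
        if not (self.train_years[1] < self.validation_years[0] <= self.validation_years[1] < self.test_years[0]):
            raise ValueError("split years must be disjoint and ordered train < validation < test")

    def split_masks(self, years: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        years = np.asarray(years)
        inside = lambda span: (years >= span[0]) & (years <= span[1])
        return inside(self.train_years), inside(self.validation_years), inside(self.test_years)


class PersonalizedAntibiogram(ClassifierMixin, BaseEstimator):
    """One selection's susceptibility classifier with built-in model selection.

    ``fit(X, y, X_val=..., y_val=...)`` runs the class-selection procedure
    described in the module docstring; without a validation set the class
    is chosen by training-set CV AUROC alone (the variant used when no
    separate validation year exists).
    """

    def __init__(
        self,
        model_classes: Sequence[str] = CLASS_ORDER,
        grids: Mapping[str, Mapping[str, list]] | None = None,
        cv_folds: int = 5,
        early_stopping_holdout: float = 0.05,
        max_boosting_rounds: int = 1000,
        early_stopping_patience: int = 10,
        seed: int = 0,
    ):
        self.model_classes = model_classes
        self.grids = grids
        self.cv_folds = cv_folds
        self.early_stopping_holdout = early_stopping_holdout
        self.max_boosting_rounds = max_boosting_rounds
        self.early_stopping_patience = early_stopping_patience
        self.seed = seed

    # -- model construction ------------------------------------------------
    def _make(self, model_class: str, params: Mapping):
        if model_class == "l1":
            return LogisticRegression(
                l1_ratio=1.0, solver="liblinear", max_iter=2000,
                random_state=self.seed, **params,
            )
        if model_class == "l2":
            return LogisticRegression(
                l1_ratio=0.0, solver="liblinear", max_iter=2000,
                random_state=self.seed, **params,
            )
        if model_class == "rf":
            return RandomForestClassifier(random_state=self.seed, n_jobs=1, **params)
        if model_class == "gbt":
            return lgb.LGBMClassifier(
                n_estimators=self.max_boosting_rounds,
                random_state=self.seed, verbose=-1, **params,
            )
        raise ValueError(f"unknown model class {model_class!r}")

    def _fit_one(self, model_class: str, params: Mapping, X, y):
        model = self._make(model_class, params)
        if model_class == "gbt":
            X_fit, X_es, y_fit, y_es = train_test_split(
                X, y, test_size=self.early_stopping_holdout,
                stratify=y, random_state=self.seed,
            )
            model.fit(
                X_fit, y_fit,
                eval_set=[(X_es, y_es)], eval_metric="binary_logloss",
                callbacks=[lgb.early_stopping(self.early_stopping_patience, verbose=False)],
            )
        else:
            model.fit(X, y)
        return model

    def _cv_auroc(self, model_class: str, params: Mapping, X, y) -> float:
        skf = StratifiedKFold(n_splits=self.cv_folds, shuffle=True, random_state=self.seed)
        scores = []
        for tr, te in skf.split(X, y):
            model = self._fit_one(model_class, params, X[tr], y[tr])
            scores.append(roc_auc_score(y[te], model.predict_proba(X[te])[:, 1]))
        return float(np.mean(scores))

    def _grid_search(self, model_class: str, X, y) -> tuple[dict, float]:
        grids = self.grids if self.grids is not None else default_grids()
        best_params, best_score = None, -np.inf
        for params in ParameterGrid(dict(grids[model_class])):
            score = self._cv_auroc(model_class, params, X, y)
            if score > best_score:  # first-best wins on exact ties (fixed grid order)
                best_params, best_score = params, score
        return best_params, best_score

    # -- the selection procedure -------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None) -> "PersonalizedAntibiogram":
        X = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X)
        y = np.asarray(y).astype(int)
        for split_name, labels in (("training", y), ("validation", y_val)):
            if labels is not None and len(np.unique(labels)) < 2:
                raise ValueError(f"{split_name} split contains a single class")

        per_class: dict[str, dict] = {}
        for mc in self.model_classes:
            params, cv_score = self._grid_search(mc, X, y)
            per_class[mc] = {"params": params, "cv_auroc": cv_score}

        if X_val is not None:
            for mc, rec in per_class.items():
                model = self._fit_one(mc, rec["params"], X, y)
                rec["validation_auroc"] = roc_auc_score(
                    y_val, model.predict_proba(X_val)[:, 1]
                )
            key = "validation_auroc"
        else:
            key = "cv_auroc"

        order = {mc: i for i, mc in enumerate(CLASS_ORDER)}
        self.best_class_ = max(
            per_class, key=lambda mc: (per_class[mc][key], -order[mc])
        )
        self.selection_report_ = per_class

        if X_val is not None:
            # re-tune the winning class on train+validation, then final fit
            X_full = sp.vstack([X, X_val]) if sp.issparse(X) else np.vstack([X, X_val])
            y_full = np.concatenate([y, np.asarray(y_val).astype(int)])
        else:
            X_full, y_full = X, y
        self.best_params_, self.retuned_cv_auroc_ = self._grid_search(self.best_class_, X_full, y_full)
        self.model_ = self._fit_one(self.best_class_, self.best_params_, X_full, y_full)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.model_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def bootstrap_metrics(
    y_true: np.ndarray, scores: np.ndarray, reps: int = 1000, seed: int = 0
) -> dict:
    """AUROC and average precision with 95% percentile bootstrap CIs.

    Resamples test rows with replacement; resamples that lose one of the
    classes are skipped. With a single class in the original labels the
    metrics are undefined and reported as NaN.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        warnings.warn("test labels contain a single class; metrics undefined")
        nan_ci = (float("nan"), float("nan"))
        return {"auroc": float("nan"), "auroc_ci": nan_ci,
                "average_precision": float("nan"), "ap_ci": nan_ci, "n": len(y_true)}
    auroc = float(roc_auc_score(y_true, scores))
    ap = float(average_precision_score(y_true, scores))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(y_true), size=(reps, len(y_true)))
    boot_auc, boot_ap = [], []
    for rep in idx:
        yb = y_true[rep]
        if yb.min() == yb.max():
            continue
        sb = scores[rep]
        boot_auc.append(roc_auc_score(yb, sb))
        boot_ap.append(average_precision_score(yb, sb))
    ci = lambda v: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
    return {
        "auroc": auroc, "auroc_ci": ci(boot_auc),
        "average_precision": ap, "ap_ci": ci(boot_ap),
        "n": len(y_true),
    }


@dataclass
class AntibiogramSuite:
    """Fitted per-selection models plus their test metrics and predictions."""

    models: dict[str, PersonalizedAntibiogram]
    metrics: pd.DataFrame  # one row per selection
    phi_test: pd.DataFrame  # N_test x M predicted coverage probabilities

    def predict_phi(self, X, index) -> pd.DataFrame:
        cols = {name: m.predict_proba(X)[:, 1] for name, m in self.models.items()}
        return pd.DataFrame(cols, index=index)


def fit_antibiogram_suite(
    X_all: sp.spmatrix,
    labels: pd.DataFrame,
    years: np.ndarray,
    plan: ModelSelectionPlan,
) -> AntibiogramSuite:
    """Fit one classifier per label column under the plan's temporal splits.

    Rows with a missing label for a given selection are dropped for that
    selection only. ``X_all`` rows must align with ``labels`` rows and
    ``years``. Test predictions are produced for *all* test rows (the
    allocation step needs the full probability matrix).
    """
    train_m, val_m, test_m = plan.split_masks(years)
    if not (train_m.any() and val_m.any() and test_m.any()):
        raise ValueError("one of the temporal splits is empty")
    X_all = sp.csr_matrix(X_all)
    models: dict[str, PersonalizedAntibiogram] = {}
    rows = []
    phi_cols = {}
    test_index = labels.index[test_m]
    for sel in labels.columns:
        col = labels[sel].to_numpy(dtype=float)
        have = ~np.isnan(col)
        tr, va, te = train_m & have, val_m & have, test_m & have
        for split_name, mask in (("training", tr), ("validation", va)):
            u = np.unique(col[mask])
            if len(u) < 2:
                raise ValueError(f"selection {sel!r}: {split_name} split has a single class")
        est = PersonalizedAntibiogram(
            model_classes=plan.model_classes, grids=plan.grids, cv_folds=plan.cv_folds,
            early_stopping_holdout=plan.early_stopping_holdout,
            max_boosting_rounds=plan.max_boosting_rounds,
            early_stopping_patience=plan.early_stopping_patience, seed=plan.seed,
        )
        est.fit(X_all[tr], col[tr], X_val=X_all[va], y_val=col[va])
        models[sel] = est
        scores_te = est.predict_proba(X_all[te])[:, 1]
        m = bootstrap_metrics(col[te], scores_te, reps=plan.bootstrap_reps, seed=plan.seed)
        rows.append({
            "selection": sel, "best_model_class": est.best_class_,
            "prevalence": float(np.nanmean(col[te])),
            "average_precision": m["average_precision"],
            "ap_ci_low": m["ap_ci"][0], "ap_ci_high": m["ap_ci"][1],
            "auroc": m["auroc"], "auroc_ci_low": m["auroc_ci"][0],
            "auroc_ci_high": m["auroc_ci"][1], "n_test": m["n"],
        })
        phi_cols[sel] = est.predict_proba(X_all[test_m])[:, 1]
    metrics = pd.DataFrame(rows).set_index("selection")
    phi_test = pd.DataFrame(phi_cols, index=test_index)
    return AntibiogramSuite(models=models, metrics=metrics, phi_test=phi_test)
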