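"""Censored-label sensitivity analysis with inverse probability weighting.

At prediction time it is unknown whether cultures will return positive, so
the deployment population includes admissions whose coverage labels are
never observed. Admissions fall into three buckets:

* **bucket 1** — positive cultures: labels observed from susceptibility
  testing;
* **bucket 2** — negative cultures flagged by a strict rule-based
  electronic phenotype as truly uninfected: labels observed and positive
  for every selection (no infection means any empiric choice "covers");
* **bucket 3** — negative cultures not flagged: infection status unknown,
  labels censored.

If censoring depends on covariates, performance measured on buckets 1∪2
is a biased estimate of deployment performance. Each observed admission is
therefore weighted by the inverse of its probability of being observed,
estimated by a random-forest classifier on the same feature matrix (fit
out-of-fold so weights are not overfit, and clipped below to keep inverse
weights bounded). Sensitivity and specificity at a threshold t are the
weighted fractions

    sens(t) = Σ_{i: Y=1} 1[f(x_i) ≥ t] / P(obs_i) ÷ Σ_{i: Y=1} 1 / P(obs_i)
    spec(t) = Σ_{i: Y=0} 1[f(x_i) <  t] / P(obs_i) ÷ Σ_{i: Y=0} 1 / P(obs_i)

(the specificity normalizer sums over the negatives — the printed formula
reuses the name W_P for it), and the IPW ROC curve / AUROC follow by
sweeping t over every distinct score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .cohort import PatientInfection
from .labeling import CONTAMINANT_ORGANISMS, NO_GROWTH, SusceptibilityLabelMatrix


@dataclass
class PhenotypeRuleSet:
    """Strict uninfected phenotype, prioritizing positive predictive value."""

    culture_negativity_window_days: float = 14.0
    max_antibiotic_duration_hours: float = 24.0
    no_restart_window_days: float = 14.0
    infection_code_prefixes: tuple[str, ...] = ("ICD_INF",)
    require_survival: bool = True

    def __post_init__(self) -> None:
        if min(self.culture_negativity_window_days, self.max_antibiotic_duration_hours,
               self.no_restart_window_days) <= 0:
            raise ValueError("phenotype windows must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PhenotypeRuleSet":
        import yaml

        raw = yaml.safe_load(open(path)) or {}
        if "infection_code_prefixes" in raw:
            raw["infection_code_prefixes"] = tuple(raw["infection_code_prefixes"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import dataclasses

        import yaml

        raw = dataclasses.asdict(self)
        raw["infection_code_prefixes"] = list(raw["infection_code_prefixes"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def phenotype_uninfected(admission: PatientInfection, rules: PhenotypeRuleSet) -> bool:
    """True iff the admission meets every uninfected criterion.

    Criteria: no positive culture within the negativity window (cultures
    growing only contaminants count as negative); antibiotics never
    administered, or stopped within the duration limit of starting and not
    restarted for the no-restart window; no infection-related diagnosis
    codes for the admission; the patient survived. Missing required fields
    raise — an admission is never silently classified uninfected.
    """
    for fld in ("cultures", "antibiotics_administered", "coded_events"):
        if getattr(admission, fld) is None:
            raise ValueError(f"{admission.infection_id}: required field {fld!r} is missing")
    if admission.died_during_admission is None or admission.infection_icd_flag is None:
        raise ValueError(f"{admission.infection_id}: outcome fields missing")

    window = timedelta(days=rules.culture_negativity_window_days)
    for c in admission.cultures:
        if c.organism != NO_GROWTH and c.organism not in CONTAMINANT_ORGANISMS:
            return False  # positive growth within the admission window
    _ = window  # cultures in this data model all fall inside the admission window

    admins = sorted(admission.antibiotics_administered, key=lambda a: a[1])
    if admins:
        first_start = admins[0][1]
        cutoff = first_start + timedelta(hours=rules.max_antibiotic_duration_hours)
        course = [a for a in admins if a[1] <= cutoff]
        restarts = [a for a in admins if a[1] > cutoff]
        if any(stop > cutoff for _, _, stop in course):
            return False
        course_end = max(stop for _, _, stop in course)
        restart_limit = course_end + timedelta(days=rules.no_restart_window_days)
        if any(start <= restart_limit for _, start, _ in restarts):
            return False
        if restarts:  # restarted at all, even late: stay conservative
            return False

    if admission.infection_icd_flag:
        return False
    if any(
        code.startswith(rules.infection_code_prefixes) and cat == "diagnosis"
        for code, cat, _ in admission.coded_events
    ):
        return False
    if rules.require_survival and admission.died_during_admission:
        return False
    return True


@dataclass
class BucketAssignment:
    """Bucket per admission and the observability indicator Obs = (bucket != 3)."""

    table: pd.DataFrame  # index infection_id; columns: bucket, observed

    @property
    def observed(self) -> pd.Series:
        return self.table["observed"]

    def counts(self) -> pd.Series:
        return self.table["bucket"].value_counts().sort_index()


def assign_buckets(
    cohort: Sequence[PatientInfection], rules: PhenotypeRuleSet | None = None
) -> BucketAssignment:
    """Bucket 1: positive culture; 2: negative + phenotype-uninfected; 3: rest."""
    rules = rules if rules is not None else PhenotypeRuleSet()
    rows = []
    for adm in cohort:
        grown = [c.organism for c in adm.cultures if c.organism != NO_GROWTH]
        true_growth = [o for o in grown if o not in CONTAMINANT_ORGANISMS]
        if true_growth:
            bucket = 1
        elif phenotype_uninfected(adm, rules):
            bucket = 2
        else:
            bucket = 3
        rows.append({"infection_id": adm.infection_id, "bucket": bucket, "observed": bucket != 3})
    return BucketAssignment(table=pd.DataFrame(rows).set_index("infection_id"))


def sensitivity_label_matrix(
    base: SusceptibilityLabelMatrix,
    buckets: BucketAssignment,
    selections: list[str],
) -> SusceptibilityLabelMatrix:
    """Updated labelling schema for the sensitivity analysis.

    Bucket-1 rows keep their culture-derived labels, bucket-2 rows get a
    positive label for every selection (provenance ``phenotype_positive``),
    bucket-3 rows are all-missing.
    """
    index = buckets.table.index
    labels = pd.DataFrame(np.nan, index=index, columns=selections, dtype=float)
    prov = pd.DataFrame("", index=index, columns=selections)
    b1 = buckets.table["bucket"] == 1
    common = base.labels.index.intersection(index[b1])
    labels.loc[common, selections] = base.labels.loc[common, selections].to_numpy()
    prov.loc[common, selections] = base.provenance.loc[common, selections].to_numpy()
    b2 = index[buckets.table["bucket"] == 2]
    labels.loc[b2, :] = 1.0
    prov.loc[b2, :] = "phenotype_positive"
    return SusceptibilityLabelMatrix(labels=labels, provenance=prov)


class PropensityModel(BaseEstimator):
    """P(label observed | features), via an out-of-fold random forest.

    ``fit_predict`` returns out-of-fold probabilities for every row, so
    downstream inverse weights are not overfit; probabilities are clipped
    below at ``clip`` to keep the weights bounded.
    """

    def __init__(self, n_estimators: int = 200, min_samples_leaf: int = 5,
                 cv: int = 5, clip: float = 0.01, seed: int = 0):
        self.n_estimators = n_estimators
        self.min_samples_leaf = min_samples_leaf
        self.cv = cv
        self.clip = clip
        self.seed = seed

    def fit_predict(self, X, observed: np.ndarray) -> np.ndarray:
        observed = np.asarray(observed).astype(int)
        if observed.min() == observed.max():
            if observed.min() == 1:
                warnings.warn("all rows observed; propensities degenerate at 1.0")
                return np.ones(len(observed))
            raise ValueError("no observed rows; propensity undefined")
        rf = RandomForestClassifier(
            n_estimators=self.n_estimators, min_samples_leaf=self.min_samples_leaf,
            random_state=self.seed, n_jobs=1,
        )
        skf = StratifiedKFold(n_splits=self.cv, shuffle=True, random_state=self.seed)
        proba = cross_val_predict(rf, X, observed, cv=skf, method="predict_proba")[:, 1]
        self.model_ = rf.fit(X, observed)
        return np.clip(proba, self.clip, 1.0)


def fit_propensity(X, observed: np.ndarray, seed: int = 0, **kwargs) -> np.ndarray:
    """Functional wrapper: out-of-fold clipped observation propensities."""
    return PropensityModel(seed=seed, **kwargs).fit_predict(X, observed)


@dataclass
class IPWCurve:
    """IPW ROC curve traced over all distinct score thresholds."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auroc: float
    w_positives: float  # Σ 1/P over positives
    w_negatives: float  # Σ 1/P over negatives (the analogous normalizer)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })


def ipw_roc(
    scores: np.ndarray,
    labels: np.ndarray,
    propensities: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> IPWCurve:
    """Inverse-probability-weighted sensitivity/specificity curve and AUROC.

    With constant propensities the weights cancel and the curve reduces to
    the ordinary empirical ROC. Raises if either class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    p = np.asarray(propensities, dtype=float)
    if np.any(p <= 0):
        raise ValueError("propensities must be positive (clip before calling)")
    pos, neg = y == 1, y == 0
    if not pos.any() or not neg.any():
        raise ValueError("IPW ROC undefined: needs both positive and negative labels")
    w = 1.0 / p
    w_pos, w_neg = float(w[pos].sum()), float(w[neg].sum())
    if thresholds is None:
        thresholds = np.concatenate(([-np.inf], np.unique(scores), [np.inf]))
    else:
        thresholds = np.sort(np.asarray(thresholds, dtype=float))
    sens = np.array([w[pos & (scores >= t)].sum() / w_pos for t in thresholds])
    spec = np.array([w[neg & (scores < t)].sum() / w_neg for t in thresholds])
    # traverse the staircase with FPR ascending and, within tied FPR,
    # sensitivity ascending (vertical segments bottom-up)
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auroc = float(np.trapezoid(sens[order], fpr[order]))
    return IPWCurve(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auroc=auroc, w_positives=w_pos, w_negatives=w_neg,
    )


def ipw_auroc(scores, labels, propensities) -> float:
    return ipw_roc(scores, labels, propensities).auroc
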