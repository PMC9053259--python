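"""Bag-of-words EHR featurization with look-back windows.

Admissions are turned into sparse count vectors the way clinical
bag-of-words pipelines do: each (category, code) pair seen in the training
set becomes a column whose value is the number of times the code appears
in the patient's record inside a category-specific look-back window before
prediction time — the entire medical history for diagnosis codes, one year
for all other coded events. Numeric labs/vitals within 14 days of
prediction time are decile-binned using cutoffs learned on the training
split only, each (measurement, decile) pair becoming a count column.
Demographics, insurance and institution are one-hot encoded against the
training levels; age in years enters as-is. Counts are left unstandardized,
and absent features are zero — missingness is encoded implicitly.

The vocabulary is learned exclusively from training rows, so transforming
validation or test rows can never create a column the training data did
not justify (no information leakage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import PatientInfection

#: look-back windows (days); diagnoses use the entire history
DIAGNOSIS_WINDOW_DAYS = None
CATEGORICAL_WINDOW_DAYS = 365
NUMERIC_WINDOW_DAYS = 14

#: interior decile cutoffs (10th..90th percentile) -> 10 reserved bins
_DECILES = np.arange(10, 100, 10)
N_BINS = 10

_DEMOGRAPHIC_FIELDS = ("sex", "race", "ethnicity", "insurance", "institution")


@dataclass
class FeatureVocabulary:
    """Training-derived schema of the sparse feature matrix."""

    categorical_terms: list[tuple[str, str]]  # (category, code), sorted
    numeric_cutoffs: dict[str, list[float]]  # measurement -> 9 non-decreasing cutoffs
    demographic_levels: dict[str, list[str]]  # field -> observed levels

    def __post_init__(self) -> None:
        for name, cuts in self.numeric_cutoffs.items():
            if any(b < a for a, b in zip(cuts, cuts[1:])):
                raise ValueError(f"decile cutoffs for {name!r} are not non-decreasing")

    def column_names(self) -> list[str]:
        cols = [f"{cat}::{code}" for cat, code in self.categorical_terms]
        for name in sorted(self.numeric_cutoffs):
            cols += [f"num::{name}::bin{b}" for b in range(1, N_BINS + 1)]
        for fld in _DEMOGRAPHIC_FIELDS:
            cols += [f"demo::{fld}::{lvl}" for lvl in self.demographic_levels[fld]]
        cols.append("demo::age_years")
        return cols

    def to_json(self, path: str | Path) -> None:
        raw = {
            "categorical_terms": [list(t) for t in self.categorical_terms],
            "numeric_cutoffs": self.numeric_cutoffs,
            "demographic_levels": self.demographic_levels,
        }
        Path(path).write_text(json.dumps(raw, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureVocabulary":
        raw = json.loads(Path(path).read_text())
        return cls(
            categorical_terms=[tuple(t) for t in raw["categorical_terms"]],
            numeric_cutoffs={k: list(map(float, v)) for k, v in raw["numeric_cutoffs"].items()},
            demographic_levels=raw["demographic_levels"],
        )


def assign_bin(value: float, cutoffs: Sequence[float]) -> int:
    """Decile bin in 1..10; ties at a cutoff fall to the lower bin.

    Duplicate cutoffs (heavy ties in training data) leave the intervening
    bins empty, collapsing them while keeping the 10-slot column schema.
    """
    return 1 + int(np.sum(value > np.asarray(cutoffs)))


def _in_window(ts, prediction_time, window_days) -> bool:
    if ts >= prediction_time:
        return False  # never count events at or after prediction time
    if window_days is None:
        return True
    return ts >= prediction_time - timedelta(days=window_days)


def _window_for(category: str):
    return DIAGNOSIS_WINDOW_DAYS if category == "diagnosis" else CATEGORICAL_WINDOW_DAYS


class BagOfWordsFeaturizer(TransformerMixin, BaseEstimator):
    """Sparse bag-of-words featurizer over admission event histories.

    Follows the ``fit``/``transform`` contract of a text vectorizer: ``X``
    is a sequence of :class:`~pabgram.cohort.PatientInfection`, ``fit``
    learns the vocabulary from the given (training) admissions and
    ``transform`` produces a CSR count matrix aligned to
    ``get_feature_names_out()``.
    """

    def fit(self, X: Sequence[PatientInfection], y=None) -> "BagOfWordsFeaturizer":
        terms: set[tuple[str, str]] = set()
        numeric_values: dict[str, list[float]] = {}
        demo_levels: dict[str, set[str]] = {f: set() for f in _DEMOGRAPHIC_FIELDS}
        for inf in X:
            for code, category, ts in inf.coded_events:
                if _in_window(ts, inf.prediction_time, _window_for(category)):
                    terms.add((category, code))
            for name, value, ts in inf.numeric_events:
                if _in_window(ts, inf.prediction_time, NUMERIC_WINDOW_DAYS):
                    numeric_values.setdefault(name, []).append(value)
            for fld in _DEMOGRAPHIC_FIELDS:
                demo_levels[fld].add(getattr(inf, fld))
        cutoffs = {
            name: [float(c) for c in np.percentile(vals, _DECILES)]
            for name, vals in numeric_values.items()
        }
        self.vocabulary_ = FeatureVocabulary(
            categorical_terms=sorted(terms),
            numeric_cutoffs=cutoffs,
            demographic_levels={f: sorted(demo_levels[f]) for f in _DEMOGRAPHIC_FIELDS},
        )
        self.feature_names_ = self.vocabulary_.column_names()
        self._index = {name: j for j, name in enumerate(self.feature_names_)}
        return self

    def transform(self, X: Sequence[PatientInfection]) -> sp.csr_matrix:
        if not hasattr(self, "vocabulary_"):
            raise RuntimeError("featurizer is not fitted")
        vocab = self.vocabulary_
        index = self._index
        rows, cols, vals = [], [], []
        for i, inf in enumerate(X):
            if inf.prediction_time is None:
                raise ValueError(f"{inf.infection_id}: prediction_time missing")
            counts: dict[int, float] = {}
            for code, category, ts in inf.coded_events:
                if not _in_window(ts, inf.prediction_time, _window_for(category)):
                    continue
                j = index.get(f"{category}::{code}")
                if j is not None:  # unseen-in-training codes contribute nothing
                    counts[j] = counts.get(j, 0) + 1
            for name, value, ts in inf.numeric_events:
                if name not in vocab.numeric_cutoffs:
                    continue
                if not _in_window(ts, inf.prediction_time, NUMERIC_WINDOW_DAYS):
                    continue
                b = assign_bin(value, vocab.numeric_cutoffs[name])
                j = index[f"num::{name}::bin{b}"]
                counts[j] = counts.get(j, 0) + 1
            for fld in _DEMOGRAPHIC_FIELDS:
                j = index.get(f"demo::{fld}::{getattr(inf, fld)}")
                if j is not None:  # unknown level at test time -> all-zero block
                    counts[j] = 1
            counts[index["demo::age_years"]] = inf.age_years
            rows.extend([i] * len(counts))
            cols.extend(counts.keys())
            vals.extend(counts.values())
        return sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(X), len(self.feature_names_)), dtype=np.float64
        )

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.feature_names_, dtype=object)


def fit_vocabulary(training_cohort: Sequence[PatientInfection]) -> FeatureVocabulary:
    """Functional wrapper over :class:`BagOfWordsFeaturizer` fitting."""
    return BagOfWordsFeaturizer().fit(training_cohort).vocabulary_


def transform(cohort: Sequence[PatientInfection], vocabulary: FeatureVocabulary) -> sp.csr_matrix:
    """Transform with a previously learned vocabulary."""
    fz = BagOfWordsFeaturizer()
    fz.vocabulary_ = vocabulary
    fz.feature_names_ = vocabulary.column_names()
    fz._index = {name: j for j, name in enumerate(fz.feature_names_)}
    return fz.transform(cohort)
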