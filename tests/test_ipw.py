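"""Electronic phenotype, buckets, propensities, and IPW ROC estimation."""

from datetime import timedelta

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from pabgram.cohort import GeneratorConfig, generate_cohort
from pabgram.ipw import (
    PhenotypeRuleSet,
    assign_buckets,
    fit_propensity,
    ipw_auroc,
    ipw_roc,
    phenotype_uninfected,
    sensitivity_label_matrix,
)
from pabgram.labeling import SusceptibilityLabelMatrix

from conftest import PT, culture, make_infection

RULES = PhenotypeRuleSet()


def _negative(**kw):
    kw.setdefault("cultures", [culture("no growth")])
    return make_infection(**kw)


class TestPhenotype:
    def test_clean_negative_admission_is_uninfected(self):
        adm = _negative(administrations=[], infection_icd_flag=False, died=False)
        assert phenotype_uninfected(adm, RULES)

    def test_antibiotics_beyond_24h_fail(self):
        adm = _negative(administrations=[("ceftriaxone", PT, PT + timedelta(hours=48))])
        assert not phenotype_uninfected(adm, RULES)

    def test_stopped_within_24h_passes(self):
        adm = _negative(administrations=[("ceftriaxone", PT, PT + timedelta(hours=12))])
        assert phenotype_uninfected(adm, RULES)

    def test_restart_within_two_weeks_fails(self):
        adm = _negative(administrations=[
            ("ceftriaxone", PT, PT + timedelta(hours=10)),
            ("ceftriaxone", PT + timedelta(days=4), PT + timedelta(days=5)),
        ])
        assert not phenotype_uninfected(adm, RULES)

    def test_positive_growth_fails(self):
        adm = make_infection([culture("Escherichia coli", {"ceftriaxone": "S"})])
        assert not phenotype_uninfected(adm, RULES)

    def test_cons_only_growth_counts_as_negative(self):
        adm = make_infection(
            [culture("Coagulase-negative Staphylococci", {"vancomycin": "S"}, "blood")],
            administrations=[],
        )
        assert phenotype_uninfected(adm, RULES)

    def test_death_fails(self):
        adm = _negative(died=True)
        assert not phenotype_uninfected(adm, RULES)

    def test_infection_icd_fails(self):
        adm = _negative(infection_icd_flag=True)
        assert not phenotype_uninfected(adm, RULES)
        adm2 = _negative(coded_events=[("ICD_INF_SEPSIS", "diagnosis", PT + timedelta(days=1))])
        assert not phenotype_uninfected(adm2, RULES)

    def test_missing_required_field_raises(self):
        adm = _negative()
        adm.antibiotics_administered = None
        with pytest.raises(ValueError, match="missing"):
            phenotype_uninfected(adm, RULES)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            PhenotypeRuleSet(max_antibiotic_duration_hours=0)

    def test_rules_yaml_round_trip(self, tmp_path):
        rules = PhenotypeRuleSet(max_antibiotic_duration_hours=12.0,
                                 infection_code_prefixes=("ICD_INF", "ICD_SEP"))
        rules.to_yaml(tmp_path / "rules.yaml")
        back = PhenotypeRuleSet.from_yaml(tmp_path / "rules.yaml")
        assert back == rules


class TestBuckets:
    def test_positive_culture_always_bucket_one(self):
        adm = make_infection(
            [culture("Escherichia coli", {"ceftriaxone": "S"})],
            administrations=[], infection_icd_flag=False, died=False,
        )
        buckets = assign_buckets([adm])
        assert buckets.table["bucket"].tolist() == [1]

    def test_no_negative_cultures_means_all_observed(self):
        cfg = GeneratorConfig(n_patients=120, negative_culture_rate=0.0,
                              contaminant_rate=0.0, seed=6)
        buckets = assign_buckets(generate_cohort(cfg))
        assert (buckets.table["bucket"] == 1).all()
        assert buckets.observed.all()

    def test_generated_cohort_produces_all_three_buckets(self, small_cohort):
        counts = assign_buckets(small_cohort).counts()
        assert set(counts.index) == {1, 2, 3}

    def test_bucket_two_rows_all_positive_labels(self, small_cohort, small_config):
        from pabgram.cohort import analysis_set
        from pabgram.labeling import build_label_matrix

        retained = analysis_set(small_cohort)
        base = build_label_matrix(retained, small_config.antibiotics, small_config.rule_table)
        buckets = assign_buckets(small_cohort)
        sens = sensitivity_label_matrix(base, buckets, small_config.selection_names)
        b2 = buckets.table.index[buckets.table["bucket"] == 2]
        assert (sens.labels.loc[b2] == 1.0).all().all()
        assert (sens.provenance.loc[b2] == "phenotype_positive").all().all()
        b3 = buckets.table.index[buckets.table["bucket"] == 3]
        assert sens.labels.loc[b3].isna().all().all()


class TestPropensity:
    def test_all_observed_degenerates_to_one(self):
        X = np.random.default_rng(0).random((40, 3))
        with pytest.warns(UserWarning, match="degenerate"):
            p = fit_propensity(X, np.ones(40))
        assert (p == 1.0).all()

    def test_independent_censoring_recovers_marginal_rate(self):
        rng = np.random.default_rng(1)
        X = rng.random((1500, 4))
        obs = rng.random(1500) < 0.7
        p = fit_propensity(X, obs, seed=0)
        assert abs(p.mean() - 0.7) < 0.05

    def test_covariate_driven_censoring_detected(self):
        rng = np.random.default_rng(2)
        X = rng.random((1500, 4))
        obs = rng.random(1500) < (0.2 + 0.7 * X[:, 0])
        p = fit_propensity(X, obs, seed=0)
        assert roc_auc_score(obs.astype(int), p) > 0.55

    def test_propensities_respect_clip(self):
        rng = np.random.default_rng(3)
        X = rng.random((400, 2))
        obs = rng.random(400) < 0.5
        p = fit_propensity(X, obs, clip=0.1)
        assert p.min() >= 0.1


class TestIPWROC:
    def test_hand_computed_sensitivity(self):
        # positives (score, propensity) = (0.9, 0.5) and (0.3, 1.0); at
        # t=0.5 only the first counts: (1/0.5)/(1/0.5 + 1/1.0) = 2/3
        scores = np.array([0.9, 0.3, 0.1])
        labels = np.array([1, 1, 0])
        prop = np.array([0.5, 1.0, 1.0])
        curve = ipw_roc(scores, labels, prop, thresholds=np.array([0.5]))
        assert curve.sensitivity[0] == pytest.approx(2 / 3)

    def test_constant_propensity_reduces_to_unweighted(self):
        rng = np.random.default_rng(0)
        scores = rng.random(300)
        labels = (rng.random(300) < 0.4).astype(int)
        auc = ipw_auroc(scores, labels, np.full(300, 0.37))
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)

    def test_matches_sample_weighted_reference(self):
        # independent oracle: sklearn's weighted AUROC with weights 1/p
        rng = np.random.default_rng(4)
        scores = rng.random(500)
        labels = (rng.random(500) < 0.5).astype(int)
        prop = rng.uniform(0.2, 1.0, size=500)
        auc = ipw_auroc(scores, labels, prop)
        ref = roc_auc_score(labels, scores, sample_weight=1.0 / prop)
        assert auc == pytest.approx(ref, abs=1e-10)

    def test_boundary_thresholds(self):
        scores = np.array([0.2, 0.8, 0.5, 0.6])
        labels = np.array([0, 1, 1, 0])
        curve = ipw_roc(scores, labels, np.full(4, 0.5))
        assert curve.sensitivity[0] == 1.0 and curve.specificity[0] == 0.0  # t = -inf
        assert curve.sensitivity[-1] == 0.0 and curve.specificity[-1] == 1.0  # t = +inf

    def test_curve_monotonicity(self):
        rng = np.random.default_rng(5)
        scores = rng.random(200)
        labels = (rng.random(200) < 0.5).astype(int)
        prop = rng.uniform(0.1, 1.0, 200)
        curve = ipw_roc(scores, labels, prop)
        assert (np.diff(curve.sensitivity) <= 1e-12).all()
        assert (np.diff(curve.specificity) >= -1e-12).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            ipw_roc(np.array([0.1, 0.2]), np.array([1, 1]), np.array([1.0, 1.0]))

    def test_nonpositive_propensity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ipw_roc(np.array([0.1, 0.2]), np.array([1, 0]), np.array([0.0, 1.0]))
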