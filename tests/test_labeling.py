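"""Coverage labelling: contaminant exclusion, imputation rules, OR-logic."""

import numpy as np
import pytest

from pabgram.cohort import SelectionSpec, default_selections
from pabgram.labeling import (
    ImputationRuleTable,
    RuleConflictError,
    build_label_matrix,
    coverage_label,
    default_rule_table,
    drop_contaminant_cultures,
    impute_call,
)

from conftest import culture, make_infection

RULES = default_rule_table()
CEFTRIAXONE = SelectionSpec("ceftriaxone", ("ceftriaxone",), 5)
VANC_CEFTRIAXONE = SelectionSpec(
    "vancomycin + ceftriaxone", ("vancomycin", "ceftriaxone"), 9
)


class TestContaminantExclusion:
    def test_cons_only_culture_is_excluded(self):
        cohort = [make_infection([culture("Coagulase-negative Staphylococci", {"vancomycin": "S"}, "blood")])]
        assert drop_contaminant_cultures(cohort) == []

    def test_mixed_culture_is_retained_and_cons_isolate_ignored(self):
        inf = make_infection([
            culture("Coagulase-negative Staphylococci", {"vancomycin": "R"}, "blood"),
            culture("Escherichia coli", {"ceftriaxone": "S"}),
        ])
        kept = drop_contaminant_cultures([inf])
        assert kept == [inf]
        # the CoNS vancomycin-R call must not defeat coverage
        label, _ = coverage_label(inf, CEFTRIAXONE, RULES)
        assert label == 1.0

    def test_negative_culture_admission_untouched(self):
        inf = make_infection([culture("no growth")])
        assert drop_contaminant_cultures([inf]) == [inf]


class TestImputation:
    @pytest.mark.parametrize(
        "organism, antibiotic, observed, expected",
        [
            ("Pseudomonas aeruginosa", "cefazolin", {}, "R"),
            ("Pseudomonas aeruginosa", "ceftriaxone", {}, "R"),
            ("Escherichia coli", "vancomycin", {}, "R"),  # Gram-negative rod
            ("Streptococcus agalactiae", "cefazolin", {}, "S"),
            # susceptible to first-generation cephalosporin -> later generations
            ("Escherichia coli", "ceftriaxone", {"cefazolin": "S"}, "S"),
            ("Escherichia coli", "cefepime", {"cefazolin": "S"}, "S"),
            # contrapositive: resistant at a later generation -> earlier ones
            ("Escherichia coli", "cefazolin", {"ceftriaxone": "R"}, "R"),
            # no applicable rule
            ("Escherichia coli", "meropenem", {}, "missing"),
            # earlier-generation resistance says nothing about later generations
            ("Escherichia coli", "ceftriaxone", {"cefazolin": "R"}, "missing"),
        ],
    )
    def test_rule_firing(self, organism, antibiotic, observed, expected):
        assert impute_call(organism, antibiotic, observed, RULES) == expected

    def test_conflicting_class_inference_raises(self):
        observed = {"cefazolin": "S", "cefepime": "R"}
        with pytest.raises(RuleConflictError, match="cefazolin.*cefepime|cefepime.*cefazolin"):
            impute_call("Escherichia coli", "ceftriaxone", observed, RULES)

    def test_rule_table_rejects_contradictory_intrinsic_rules(self):
        with pytest.raises(RuleConflictError):
            ImputationRuleTable(
                intrinsic_resistance=[("Streptococcus agalactiae", "cefazolin")],
                intrinsic_susceptibility=[("Streptococcus agalactiae", "cephalosporin")],
                class_hierarchy={"cephalosporin": [{"generation": 1, "members": ["cefazolin"]}]},
            )

    def test_hierarchy_generations_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            ImputationRuleTable(
                class_hierarchy={"c": [{"generation": 3, "members": ["a"]},
                                       {"generation": 1, "members": ["b"]}]}
            )


class TestCoverageLabel:
    def test_combination_covers_via_one_component(self):
        # E. coli: ceftriaxone S observed, vancomycin R by imputation -> combo covers
        inf = make_infection([culture("Escherichia coli", {"ceftriaxone": "S"})])
        label, prov = coverage_label(inf, VANC_CEFTRIAXONE, RULES)
        assert label == 1.0

    def test_conjunction_over_organisms_fails(self):
        inf = make_infection([
            culture("Escherichia coli", {"ceftriaxone": "S"}),
            culture("Enterococcus faecalis", {"vancomycin": "S"}),  # ceftriaxone intrinsic R
        ])
        label, _ = coverage_label(inf, CEFTRIAXONE, RULES)
        assert label == 0.0

    def test_intermediate_counts_as_not_susceptible(self):
        inf = make_infection([culture("Escherichia coli", {"ceftriaxone": "I"})])
        label, _ = coverage_label(inf, CEFTRIAXONE, RULES)
        assert label == 0.0

    def test_unresolvable_call_gives_missing(self):
        inf = make_infection([culture("Escherichia coli", {"ceftriaxone": "not_tested"})])
        label, prov = coverage_label(inf, SelectionSpec("meropenem", ("meropenem",), 7), RULES)
        assert np.isnan(label) and prov == ""

    def test_observed_s_short_circuits_missing_component(self):
        # one covering drug observed: residual missingness cannot matter
        inf = make_infection([culture("Escherichia coli", {"ceftriaxone": "S", "vancomycin": "not_tested"})])
        label, _ = coverage_label(inf, VANC_CEFTRIAXONE, RULES)
        assert label == 1.0


class TestLabelMatrix:
    def test_shape_and_combination_count(self, small_cohort, small_config):
        from pabgram.cohort import analysis_set

        retained = analysis_set(small_cohort)
        m = build_label_matrix(retained, small_config.antibiotics, RULES)
        assert m.labels.shape == (len(retained), 12)
        assert sum(s.is_combination for s in small_config.antibiotics) == 4

    def test_all_susceptible_toy_cohort_is_all_ones(self):
        cohort = [
            make_infection([culture("Escherichia coli", {"ceftriaxone": "S", "vancomycin": "S"})], infection_id=f"I{i}")
            for i in range(3)
        ]
        m = build_label_matrix(cohort, [CEFTRIAXONE, VANC_CEFTRIAXONE], RULES)
        assert (m.labels.to_numpy() == 1.0).all()

    def test_or_consistency_of_combination_columns(self, small_cohort, small_config):
        from pabgram.cohort import analysis_set

        m = build_label_matrix(analysis_set(small_cohort), small_config.antibiotics, RULES)
        for spec in small_config.antibiotics:
            if not spec.is_combination:
                continue
            combo = m.labels[spec.name]
            parts = m.labels[list(spec.components)]
            both = combo.notna() & parts.notna().all(axis=1)
            expected = parts.loc[both].max(axis=1)
            assert (combo.loc[both] == expected).all(), spec.name

    def test_idempotence(self, small_cohort, small_config):
        from pabgram.cohort import analysis_set

        retained = analysis_set(small_cohort)
        m1 = build_label_matrix(retained, small_config.antibiotics, RULES)
        m2 = build_label_matrix(retained, small_config.antibiotics, RULES)
        assert m1.labels.equals(m2.labels) and m1.provenance.equals(m2.provenance)

    def test_prevalence_matches_generator_targets(self, small_cohort, small_config):
        from pabgram.cohort import analysis_set

        m = build_label_matrix(analysis_set(small_cohort), small_config.antibiotics, RULES)
        prev = m.prevalence()
        for drug, target in small_config.target_prevalence.items():
            assert abs(prev[drug] - target) < 0.05, drug  # n~400 positives

    def test_round_trip_csv(self, tmp_path, small_cohort, small_config):
        from pabgram.cohort import analysis_set
        from pabgram.labeling import SusceptibilityLabelMatrix

        m = build_label_matrix(analysis_set(small_cohort)[:30], small_config.antibiotics, RULES)
        m.to_csv(tmp_path / "l.csv", tmp_path / "p.csv")
        back = SusceptibilityLabelMatrix.from_csv(tmp_path / "l.csv", tmp_path / "p.csv")
        assert back.labels.equals(m.labels)
        assert back.provenance.equals(m.provenance)
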