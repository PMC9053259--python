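# pabgram — personalized antibiograms for antibiotic selection

When a patient presents with a suspected infection, antibiotics must be
chosen *empirically* — days before microbial cultures identify the organism
and its susceptibilities. Clinicians balance broad-spectrum coverage (safer
for the individual, costly for resistance stewardship) against narrower,
more precise therapy. `pabgram` implements a complete, testable pipeline
for studying this trade-off with machine learning on electronic health
record (EHR) data:

1. **Personalized antibiograms** — per-patient binary classifiers
   f̂_j(x) ∈ [0, 1] estimating the probability that antibiotic selection
   *j* covers the infection of a patient with EHR feature vector *x*
   (a selection covers an infection when every cultured organism is
   susceptible to at least one of its drugs; intermediate counts as not
   susceptible).
2. **Budget-constrained allocation** — with Φ ∈ ℝ^{N×M} the predicted
   coverage probabilities over a held-out cohort and K_j a fixed usage
   budget per selection, solve

   ```
   maximize_S  Σ_i Σ_j  φ_ij s_ij
   subject to  Σ_j s_ij = 1        (one selection per admission)
               Σ_i s_ij = K_j     (selection j used exactly K_j times)
   ```

   This transportation-structured program has an integral optimum; it is
   solved exactly via Hungarian assignment on budget-expanded columns.
3. **Stewardship sweeps** — re-solve while exchanging broad-spectrum
   budget for a narrower drug one prescription at a time, tracking how far
   prescribing can be narrowed before coverage falls below the clinician
   or random baselines.
4. **Inference** — one-sided permutation tests against budget-preserving
   random allocation and stratified bootstrap against clinician
   prescribing (10,000 reps, p-values floored at "<0.0001").
5. **Censored-label sensitivity analysis** — a strict electronic phenotype
   splits negative-culture admissions into observed ("truly uninfected",
   labelled covered-by-anything) and censored buckets, and inverse
   probability weighting (weights 1/P̂(observed | x) from an out-of-fold
   random forest) estimates deployment-population ROC/AUROC:

   ```
   sens_IPW(t) = Σ_{i:Y=1} 1[f̂(x_i) ≥ t]/P̂_i  ÷  Σ_{i:Y=1} 1/P̂_i
   ```

Because real ED infection cohorts are access-restricted, the package ships
a **synthetic cohort generator** that emulates the statistical structure
the analysis needs — spectrum-ordered susceptibility profiles calibrated
to configurable per-antibiotic prevalences, covariate-driven resistance,
severity-informed clinician prescribing, missing susceptibility tests, and
covariate-dependent label censoring — with full ground truth available for
oracle baselines and bias-correction checks.

Intended users: biostatisticians and clinical-informatics researchers
studying antimicrobial stewardship decision support.

## Worked example

```python
import numpy as np
from pabgram import (
    GeneratorConfig, generate_cohort, oracle_probabilities,
    AllocationProblem, solve_allocation, coverage_rate,
    clinician_budgets, permutation_test_vs_random,
)
from pabgram.cohort import analysis_set, true_label_matrix

cfg = GeneratorConfig(n_patients=770, negative_culture_rate=0.0,
                      contaminant_rate=0.0, seed=7)
cohort = generate_cohort(cfg)
retained = analysis_set(cohort)            # positive-culture infections
truth = true_label_matrix(retained)        # N x 12 coverage labels
phi = oracle_probabilities(cfg, cohort)    # Bayes-optimal predictions

selections = list(truth.columns)
K = clinician_budgets(retained, selections)
alloc = solve_allocation(AllocationProblem(phi.to_numpy(), K, selections))

pa = coverage_rate(alloc, truth)
clin = np.mean([truth.loc[i.infection_id, i.clinician_selection] for i in retained])
res = permutation_test_vs_random(pa, truth, K, reps=10_000, seed=0)
print(f"optimized coverage {pa:.1%}, clinician {clin:.1%}, p vs random {res.p_str}")
```

Output:

```
optimized coverage 90.3%, clinician 74.3%, p vs random <0.0001
```

Reading: re-allocating the same antibiotic budget that clinicians used,
but guided by the generative model's coverage probabilities, covers 90.3%
of these infections versus 74.3% under the clinicians' own assignments,
and no budget-preserving random re-assignment out of 10,000 reached the
optimized rate. (Oracle probabilities are an upper bound; classifiers
trained on the EHR features land between the clinician and oracle rates.)

The full pipeline (simulate → label → featurize → train → allocate →
sweep → stats → ipw → report) is also exposed as a CLI:

```bash
pabgram all -o myrun --seed 3
cat myrun/report.md
```

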