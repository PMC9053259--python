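# Methods

This note documents the models, parameters, numerical choices and
limitations of `pabgram`, in the order the pipeline runs them.

## Synthetic cohort generator

The unit of observation is a *patient-infection*: one emergency-department
admission with a prediction time (the first IV/IM antibiotic order), a
history of coded and numeric events, cultures, the clinician's empiric
selection, and outcome fields.

**Latent resistance score.** Each admission draws covariates — prior
resistant cultures (Poisson, mean 0.3), prior antibiotic exposures
(Poisson, 0.8), comorbidity count (Poisson, 1.5), recent hospitalization
(Bernoulli, 0.2), age (normal, 68 ± 17 y, clipped to 18–100) — and a
latent resistance score

    z = β·x + ε,   ε ~ N(0, noise_sd²),  noise_sd = 1 by default.

Default coefficients β (config `covariate_effects`): 0.8 per prior
resistant culture, 0.35 per prior antibiotic exposure, 0.25 per
comorbidity, 0.5 for recent hospitalization, 0.1 per decade of age over
68. The covariates are also emitted as timestamped events (diagnoses over
0–5 years back, medication/micro-order events within ~2 years, labs and
vitals mostly within 14 days) so that the featurization windows are
genuinely exercised; labs/vitals additionally correlate with z and with a
severity proxy, giving the classifiers signal to find.

**Susceptibility model.** A positive culture draws one organism from a
configurable mix (default: nine species, 63% Gram-negative rods, with a
3% MRSA component). For each single drug, an infection is susceptible iff
its organism carries no intrinsic-resistance rule for that drug and
z ≤ t_drug. One shared score with per-drug thresholds makes coverage
*nested*: a drug with a higher threshold covers a superset of what a
lower-threshold drug covers among rule-free organisms — the
spectrum-consistency the analysis assumes. Thresholds are solved by
quantile matching: t_drug is the empirical quantile of z among rule-free
infections at the level that makes the overall covered fraction equal the
configured target prevalence. Default targets are a typical ED antibiogram
column, 0.23 (vancomycin) through 0.90 (piperacillin/tazobactam).
Feasibility is checked against the *configured* design (expected organism
masses): a target exceeding the rule-free mass, or a pair of
elementwise-dominating drugs whose targets contradict their spectrum
ranks, is rejected with a diagnostic. Finite-sample shortfalls in a
particular draw saturate instead of erroring.

Combination selections cover iff any component covers (OR); under the
shared score this binds at the maximum eligible component threshold, so
combination prevalence is derived, never configured. The MRSA component
is what gives vancomycin genuine add-on value in combinations: without an
organism stratum resistant to all beta-lactams but covered by vancomycin,
every combination would collapse onto its broadest component and the
broad→narrow sweeps would be vacuous.

**Laboratory calls.** Rule-constrained (intrinsically resistant or
susceptible) drug/organism pairs are recorded as `not_tested`, as labs do
not test implausible pairs — these are exactly the cells the labeler's
imputation rules recover. Rule-free calls are `S` when covered, otherwise
`I` with probability 0.15 and `R` otherwise, and are `not_tested` with
probability 0.05 (`missing_test_rate`), which produces genuinely missing
labels downstream. 4% of positive-culture admissions grow only
Coagulase-negative Staphylococci (contaminants).

**Clinician policy.** A severity proxy z + 0.7·N(0,1) is cut at terciles
into low/moderate/high tiers, each with its own selection-frequency
weights (broader therapy for sicker patients). Prescribing is therefore
informative about resistance but imperfect — clinician coverage sits a few
points above the random baseline, qualitatively matching real empiric
prescribing, without being tuned to any particular figure.

**Negative cultures and censoring.** A configurable fraction (default
0.5) of admissions culture negative; the value is a desk-scale choice — in
real ED cohorts most cultured admissions return negative, but carrying a
larger negative fraction only inflates runtime without changing the
mechanics under test. A negative-culture admission harbors a latent
infection with probability expit(a + z̃) where the intercept a is solved
(bisection) so the marginal equals `latent_infection_rate_given_negative`
(default 0.3). Latently infected admissions usually keep antibiotics
running and carry infection diagnosis codes, so the electronic phenotype
misses them; truly uninfected admissions usually stop antibiotics within
24 h. Censoring (bucket 3 membership) is therefore driven by the same
latent score the labels depend on — the setting in which naive
observed-only evaluation is biased and IPW has something to correct.

The generator retains its ground truth (latent scores, latent infection
status, true coverage per selection) on each record and in a `truth.csv`
sidecar. `oracle_probabilities` reconstructs the Bayes-optimal coverage
probabilities P(covered | x, organism) analytically from the probit
structure and verifies the cohort against the config before returning.

## Labelling

A selection covers an infection iff every retained organism is susceptible
(`S`; intermediate is not susceptible) to at least one component drug.
Cultures growing only contaminants are excluded; contaminant isolates in
mixed cultures are ignored. Missing calls are imputed by a rule table
(YAML, editable) in priority order: intrinsic resistance → intrinsic
susceptibility → cephalosporin-generation inference. The generation rule
is applied in both logically valid directions: susceptible at an earlier
generation implies susceptible later, and (contrapositive, for binary
coverage) non-susceptible at a later generation implies non-susceptible
earlier. Cells unresolved after imputation stay missing and drop that
infection from that selection's training/evaluation rows — imputation is
microbiological only, never statistical. Conflicting rule firings raise an
error naming both rules.

The shipped default table contains the classic exemplars (Pseudomonas
aeruginosa resistant to ceftriaxone/cefazolin; Gram-negative rods to
vancomycin; Streptococcus agalactiae susceptible to cephalosporins), the
enterococcal cephalosporin resistances, the MRSA beta-lactam resistances
that mirror the generator's MRSA stratum, and a three-tier cephalosporin
hierarchy (cefazolin < ceftriaxone < cefepime).

## Featurization

Bag-of-words counts over (category, code) pairs with category-specific
look-back windows: entire history for diagnoses, 365 days for other coded
events, 14 days for numeric labs/vitals. Numeric values are binned by
training-set decile cutoffs (nine interior thresholds at the 10th–90th
percentiles, ten reserved bin columns). Bin convention: value v falls in
bin 1 + #{cutoffs < v}; ties at a cutoff go to the lower bin; duplicate
cutoffs collapse bins while keeping the 10-slot schema. Demographics,
insurance and institution are one-hot encoded against training levels
(unknown test-time levels become an all-zero block); age enters in years.
Counts are unstandardized; zero encodes absence. The vocabulary is learned
from training rows only, and events at or after prediction time are never
counted — both properties are asserted by tests that mutate test rows and
observe unchanged artifacts.

## Model selection

Four model classes span the bias/variance range: L1 and L2 logistic
regression (liblinear), random forests, and LightGBM gradient-boosted
trees. Per selection: stratified 5-fold CV grid search per class on the
training years (scored by mean AUROC, first-best on ties in fixed grid
order); each class's best configuration refit on the training years and
scored on the validation year; winner by validation AUROC with exact ties
broken in the order L1 > L2 > RF > GBT (simplest first); winner re-tuned
by the same CV grid search on train+validation and finally fit there.
Without a validation year the winner is chosen by CV AUROC directly. GBT
fits always hold out a stratified 5% of their training data for early
stopping (≤1000 rounds, patience 10), with binary log-loss as the
concrete stopping metric. Classes are never re-weighted or re-sampled,
preserving probability calibration.

Default grids: C ∈ logspace(−3, 2, 7) for both logistic penalties; RF
trees {200, 500} × depth {∞, 10, 20} × min-leaf {1, 5}; GBT learning rate
{0.03, 0.1} × leaves {15, 31} × min-child {10, 50}. A reduced `desk_grids`
preset (2 configurations per class) drives the end-to-end runs. Metrics
are AUROC and average precision with 95% percentile bootstrap CIs over
1000 test resamples (resamples that lose a class are skipped; single-class
test labels report NaN).

## Allocation

The budget-constrained selection problem is a transportation LP with unit
row supplies, so an integral optimum exists; it is solved exactly by
expanding each selection column into K_j copies and running
`scipy.optimize.linear_sum_assignment` on the N×N cost matrix. A
deterministic lexicographic perturbation (+j·10⁻⁹ on column j) fixes
tie-breaking; objectives are reported on unperturbed Φ. A brute-force
enumeration oracle verifies optimality on small instances in the tests.
The analysis is restricted to test admissions whose clinician selection is
among the modelled selections and whose label row is fully resolved, so
any assignment is scoreable. Budget sweeps move one prescription at a time
(configurable step) and report the largest k keeping coverage at or above
the clinician and random baselines; the random baseline is a fixed
base-budget permutation, not re-drawn per sweep step. The broad→narrow
sweep ordering uses antibiogram values computed on train+validation
labels, never test labels.

## Inference

One-sided permutation test against random allocation: the null re-assigns
the budget multiset uniformly 10,000 times; p is the fraction of null
coverage rates ≥ observed, with no add-one correction and ties counting
against the alternative; p = 0 is reported as the floor "<1/reps" (a
string plus machine-readable flag). The clinician comparison resamples
clinician outcomes within antibiotic-selection strata (sizes preserved;
empty strata contribute nothing), same one-sided convention. Coverage
rates are lattice-valued (multiples of 1/N), so p at the null median can
sit slightly above ½ under the ≥ convention.

## Sensitivity analysis and IPW

The electronic phenotype is deliberately strict (positive predictive value
over sensitivity): no non-contaminant growth in window, antibiotics never
given or stopped within 24 h and never restarted (restarts within two
weeks fail outright; any restart fails conservatively), no
infection-related diagnosis codes (prefix-configurable, default
`ICD_INF*`) or admission flag, survival required. Missing fields raise —
an admission is never silently uninfected. Bucket 2 rows get label 1 for
every selection; bucket 3 rows are censored. Sensitivity-analysis models
are retrained on buckets 1∪2 with the updated labels and compared to the
original models alongside their IPW AUROCs.

Observation propensities come from a random forest on the same feature
matrix, predicted out-of-fold (5-fold) so the weights are not overfit, and
clipped below at 0.01 — unclipped inverse weights explode on
rare-observation strata. The IPW ROC sweeps every distinct score plus ±∞;
sensitivity uses 1[f̂ ≥ t], specificity 1[f̂ < t]; the specificity
normalizer is the sum of inverse propensities over the *negatives* (the
natural analogue of the positives' normalizer, resolving a notational
reuse in the printed estimator). AUROC integrates the staircase by
trapezoid with points ordered by (FPR, sensitivity); with constant
propensities this reproduces the unweighted empirical AUROC to machine
precision, and with inverse-propensity sample weights it matches
scikit-learn's weighted AUROC — both asserted in tests.

## Pipeline, seeds, problem sizes

A single global seed fans out to per-stage seeds through
`numpy.random.SeedSequence([seed, stage_index])`, so stages are
independently re-runnable yet jointly reproducible; the run manifest
records per-stage seeds and output hashes, and identical config+seed
reproduces artifacts byte for byte. Stage dependencies are checked and
violations name the missing stage. Exclusion counts are logged.

Problem sizes in the shipped runs are desk-scale choices: the test suite
exercises cohorts of ~10²–10⁴ admissions, 100-seed replications for the
stochastic properties (bias correction, allocation-vs-random), 500 runs
for permutation calibration, and `scripts/acceptance.py` runs a 9,000
admission cohort with the reduced grids and two test years (several
hundred allocation rows). Scaling any of these up changes runtimes, not
code paths.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis
assumes — configurable prevalences, nested spectra, covariate-driven
resistance and censoring, informative-but-imperfect clinicians — not
clinical reality: vocabularies are synthetic, organisms are a nine-species
caricature, one isolate per culture by default (`polymicrobial_rate`
exists but defaults to 0 because multi-isolate conjunctions are not part
of the calibration guarantee), and clinician behavior has no real-world
anchoring beyond its qualitative ordering. Passing tests therefore
demonstrate correctness of the machinery (labelling logic, leakage-free
featurization, exact optimization, calibrated inference, bias-correcting
IPW) on data whose ground truth is known — they do not certify model
performance or coverage improvements on any real cohort. Known
limitations shared with the underlying design: in-vitro calls are taken at
face value (no in-vivo induction), the LP is a population simulation
rather than a sequential decision rule, and IPW relies on
no-unmeasured-confounding in the observation model.
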