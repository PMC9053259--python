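"""Synthetic patient-infection cohort generator.

Emulates the statistical structure of an emergency-department infection
cohort so the whole personalized-antibiogram pipeline can be exercised
without restricted EHR data:

* each admission carries demographics, timestamped coded events (diagnoses,
  medication/lab/micro orders, procedures) and numeric measurements spread
  over look-back windows of up to five years;
* positive-culture admissions draw an organism and a latent resistance
  score ``z = beta.x + noise`` from configurable covariate effects; single
  per-antibiotic thresholds on ``z`` (solved by quantile matching against
  the configured target prevalences) produce spectrum-consistent nested
  S/I/R calls, with intrinsic-resistance rules overriding by organism;
* combination selections cover iff any component covers (OR);
* clinicians prescribe from a severity-conditioned policy, so their
  choices are informative but imperfect;
* negative-culture admissions carry a latent infection status whose
  probability increases with the same resistance score, producing
  covariate-dependent label censoring for the sensitivity analysis.

The generator also knows the ground truth (latent scores, latent infection
status, true coverage of every selection), which powers oracle baselines
and bias-correction checks that are impossible on real data.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .labeling import (
    CONTAMINANT_ORGANISMS,
    NO_GROWTH,
    ImputationRuleTable,
    default_rule_table,
    drop_contaminant_cultures,
)

CONS = "Coagulase-negative Staphylococci"


class InfeasiblePrevalenceError(ValueError):
    """Prevalence targets incompatible with the rule table / spectrum order."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionSpec:
    """An antibiotic selection: a single drug or a combination therapy."""

    name: str
    components: tuple[str, ...]
    spectrum_rank: int  # higher = broader (higher antibiogram value)

    @property
    def is_combination(self) -> bool:
        return len(self.components) > 1


@dataclass(frozen=True)
class CultureResult:
    culture_type: str  # blood | urine | csf | fluid
    organism: str  # organism name or "no growth"
    susceptibilities: Mapping[str, str]  # drug -> S | I | R | not_tested

    def __post_init__(self) -> None:
        if self.organism == NO_GROWTH and self.susceptibilities:
            raise ValueError("'no growth' culture cannot carry susceptibility calls")


@dataclass
class PatientInfection:
    """One admission-level observation (the unit of analysis)."""

    patient_id: str
    infection_id: str
    year: int
    prediction_time: datetime
    age_years: float
    sex: str
    race: str
    ethnicity: str
    insurance: str
    institution: str
    coded_events: list[tuple[str, str, datetime]]  # (code, category, timestamp)
    numeric_events: list[tuple[str, float, datetime]]
    cultures: list[CultureResult]
    clinician_selection: str | None
    antibiotics_administered: list[tuple[str, datetime, datetime]]
    infection_icd_flag: bool
    died_during_admission: bool
    # --- generator ground truth (not visible to models) ---
    latent_score: float = 0.0
    latent_infected: bool = True
    severity_tier: str = "moderate"
    covariates: dict[str, float] = field(default_factory=dict)
    true_coverage: dict[str, int] = field(default_factory=dict)

    @property
    def has_positive_culture(self) -> bool:
        return any(c.organism != NO_GROWTH for c in self.cultures)


def default_selections() -> list[SelectionSpec]:
    """Twelve ED empiric selections: eight single drugs, four combinations."""
    singles = [
        ("vancomycin", 1),
        ("ampicillin", 2),
        ("cefazolin", 3),
        ("ciprofloxacin", 4),
        ("ceftriaxone", 5),
        ("cefepime", 6),
        ("meropenem", 7),
        ("piperacillin/tazobactam", 8),
    ]
    combos = [
        ("vancomycin + ceftriaxone", ("vancomycin", "ceftriaxone"), 9),
        ("vancomycin + piperacillin/tazobactam", ("vancomycin", "piperacillin/tazobactam"), 10),
        ("vancomycin + cefepime", ("vancomycin", "cefepime"), 11),
        ("vancomycin + meropenem", ("vancomycin", "meropenem"), 12),
    ]
    specs = [SelectionSpec(n, (n,), r) for n, r in singles]
    specs += [SelectionSpec(n, comps, r) for n, comps, r in combos]
    return specs


def default_target_prevalence() -> dict[str, float]:
    """Per-single-drug covered fractions typical of an ED antibiogram."""
    return {
        "vancomycin": 0.23,
        "ampicillin": 0.43,
        "cefazolin": 0.59,
        "ciprofloxacin": 0.63,
        "ceftriaxone": 0.66,
        "cefepime": 0.80,
        "meropenem": 0.82,
        "piperacillin/tazobactam": 0.90,
    }


def default_organism_mix() -> dict[str, float]:
    return {
        "Escherichia coli": 0.40,
        "Klebsiella pneumoniae": 0.12,
        "Proteus mirabilis": 0.05,
        "Pseudomonas aeruginosa": 0.06,
        "Staphylococcus aureus": 0.10,
        "Staphylococcus aureus (MRSA)": 0.03,
        "Enterococcus faecalis": 0.10,
        "Enterococcus faecium": 0.05,
        "Streptococcus agalactiae": 0.06,
        "Streptococcus anginosus": 0.03,
    }


def default_covariate_effects() -> dict[str, float]:
    """Coefficients of the latent resistance score on generated covariates."""
    return {
        "prior_resistant_cultures": 0.8,
        "prior_antibiotic_exposures": 0.35,
        "comorbidity_count": 0.25,
        "recent_hospitalization": 0.5,
        "age_centered_decades": 0.1,
    }


def default_clinician_policy() -> dict[str, dict[str, float]]:
    """Severity-tier -> selection-frequency weights.

    Sicker (higher latent score plus noise) patients receive broader
    empiric therapy more often, so clinician prescribing is informative
    about resistance but imperfect.
    """
    return {
        "low": {
            "ceftriaxone": 0.30, "cefazolin": 0.18, "ciprofloxacin": 0.18,
            "ampicillin": 0.10, "vancomycin": 0.06, "piperacillin/tazobactam": 0.06,
            "cefepime": 0.05, "vancomycin + ceftriaxone": 0.04, "meropenem": 0.03,
        },
        "moderate": {
            "ceftriaxone": 0.20, "piperacillin/tazobactam": 0.16, "cefepime": 0.12,
            "vancomycin + ceftriaxone": 0.10, "ciprofloxacin": 0.10, "cefazolin": 0.08,
            "vancomycin": 0.08, "meropenem": 0.06, "vancomycin + piperacillin/tazobactam": 0.06,
            "ampicillin": 0.04,
        },
        "high": {
            "vancomycin + piperacillin/tazobactam": 0.30, "piperacillin/tazobactam": 0.15,
            "vancomycin + cefepime": 0.13, "cefepime": 0.10, "meropenem": 0.10,
            "vancomycin + meropenem": 0.06, "vancomycin + ceftriaxone": 0.08,
            "ceftriaxone": 0.05, "vancomycin": 0.03,
        },
    }


@dataclass
class GeneratorConfig:
    """Everything that defines the synthetic data-generating process."""

    n_patients: int = 2000
    antibiotics: list[SelectionSpec] = field(default_factory=default_selections)
    target_prevalence: dict[str, float] = field(default_factory=default_target_prevalence)
    organism_mix: dict[str, float] = field(default_factory=default_organism_mix)
    covariate_effects: dict[str, float] = field(default_factory=default_covariate_effects)
    clinician_policy: dict[str, dict[str, float]] = field(default_factory=default_clinician_policy)
    negative_culture_rate: float = 0.5
    latent_infection_rate_given_negative: float = 0.3
    year_range: tuple[int, int] = (2009, 2019)
    seed: int = 0
    # secondary knobs
    noise_sd: float = 1.0
    censoring_strength: float = 1.0  # latent-score slope of P(infected | negative culture)
    missing_test_rate: float = 0.05
    intermediate_call_rate: float = 0.15
    contaminant_rate: float = 0.04
    polymicrobial_rate: float = 0.0
    include_events: bool = True
    rule_table: ImputationRuleTable | None = None

    def __post_init__(self) -> None:
        if self.rule_table is None:
            self.rule_table = default_rule_table()
        self.validate()

    @property
    def single_drugs(self) -> list[str]:
        return [s.name for s in self.antibiotics if not s.is_combination]

    @property
    def selection_names(self) -> list[str]:
        return [s.name for s in self.antibiotics]

    def selection(self, name: str) -> SelectionSpec:
        for s in self.antibiotics:
            if s.name == name:
                return s
        raise KeyError(name)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        total = sum(self.organism_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"organism_mix probabilities sum to {total}, expected 1")
        ranks = [s.spectrum_rank for s in self.antibiotics]
        if len(set(ranks)) != len(ranks):
            raise ValueError("spectrum ranks must be a strict total order")
        singles = set(self.single_drugs)
        for s in self.antibiotics:
            if s.is_combination:
                unknown = set(s.components) - singles
                if unknown:
                    raise ValueError(
                        f"combination {s.name!r} references unknown components {sorted(unknown)}"
                    )
        for name, p in self.target_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"target_prevalence[{name!r}]={p} outside [0, 1]")
            spec = self.selection(name)
            if spec.is_combination:
                raise InfeasiblePrevalenceError(
                    f"target_prevalence may only constrain single drugs; the "
                    f"prevalence of combination {name!r} derives from the OR "
                    "of its components"
                )
        missing = set(self.single_drugs) - set(self.target_prevalence)
        if missing:
            raise ValueError(f"no target_prevalence for single drugs {sorted(missing)}")
        if not 0.0 <= self.negative_culture_rate <= 1.0:
            raise ValueError("negative_culture_rate outside [0, 1]")
        if not 0.0 <= self.latent_infection_rate_given_negative <= 1.0:
            raise ValueError("latent_infection_rate_given_negative outside [0, 1]")

    # YAML round-trip (selections flattened to plain lists) -----------------
    def to_dict(self) -> dict:
        raw = dataclasses.asdict(self)
        raw["antibiotics"] = [
            {"name": s.name, "components": list(s.components), "spectrum_rank": s.spectrum_rank}
            for s in self.antibiotics
        ]
        raw["year_range"] = list(self.year_range)
        raw.pop("rule_table")
        return raw

    @classmethod
    def from_dict(cls, raw: Mapping) -> "GeneratorConfig":
        raw = dict(raw)
        if "antibiotics" in raw:
            raw["antibiotics"] = [
                SelectionSpec(a["name"], tuple(a["components"]), int(a["spectrum_rank"]))
                for a in raw["antibiotics"]
            ]
        if "year_range" in raw:
            raw["year_range"] = tuple(raw["year_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

def _organism_status(config: GeneratorConfig) -> tuple[dict[str, dict[str, str]], ImputationRuleTable]:
    """Per (organism, drug): 'R' (intrinsic), 'S' (intrinsic) or 'free'."""
    rules = config.rule_table
    assert rules is not None
    status: dict[str, dict[str, str]] = {}
    organisms = list(config.organism_mix) + [CONS]
    for org in organisms:
        status[org] = {}
        for drug in config.single_drugs:
            if rules.is_intrinsically_resistant(org, drug):
                status[org][drug] = "R"
            elif rules.is_intrinsically_susceptible(org, drug):
                status[org][drug] = "S"
            else:
                status[org][drug] = "free"
    return status, rules


def _calibrate_thresholds(
    z: np.ndarray, organisms: np.ndarray, config: GeneratorConfig
) -> dict[str, float]:
    """Solve per-drug thresholds on the latent score by quantile matching.

    ``z`` and ``organisms`` are the retained positive-culture infections.
    An infection is susceptible to a free (no intrinsic rule) drug iff its
    latent score is at or below the drug's threshold, so the threshold is
    the empirical quantile of ``z`` among rule-free infections at the level
    that makes the overall covered fraction hit the target.
    """
    status, _ = _organism_status(config)
    n = len(z)
    if n == 0:
        raise ValueError("cannot calibrate thresholds without positive-culture infections")
    thresholds: dict[str, float] = {}
    for drug in config.single_drugs:
        target = config.target_prevalence[drug]
        # feasibility is a property of the configured design (expected
        # organism masses), not of one finite draw
        exp_s = sum(p for o, p in config.organism_mix.items() if status[o][drug] == "S")
        exp_free = sum(p for o, p in config.organism_mix.items() if status[o][drug] == "free")
        if exp_free <= 0:
            if abs(target - exp_s) > 1e-9:
                raise InfeasiblePrevalenceError(
                    f"{drug!r}: no rule-free organism mass but target {target} "
                    f"differs from intrinsic-susceptible mass {exp_s:.3f}"
                )
            thresholds[drug] = -np.inf
            continue
        exp_level = (target - exp_s) / exp_free
        if exp_level < -1e-9 or exp_level > 1 + 1e-9:
            raise InfeasiblePrevalenceError(
                f"{drug!r}: target prevalence {target} infeasible — intrinsic "
                f"susceptible mass {exp_s:.3f} and rule-free mass {exp_free:.3f} "
                f"imply a required conditional rate of {exp_level:.3f}"
            )
        # quantile-match against the realized draw; finite-sample shortfalls
        # in the free mass saturate rather than erroring
        stat = np.array([status[o][drug] for o in organisms])
        free = stat == "free"
        n_intr_s = int((stat == "S").sum())
        n_free = int(free.sum())
        if n_free == 0:
            thresholds[drug] = -np.inf
            continue
        level = np.clip((target * n - n_intr_s) / n_free, 0.0, 1.0)
        thresholds[drug] = float(np.quantile(z[free], level))
    _check_spectrum_consistency(config, thresholds, status)
    return thresholds


def dominance_pairs(config: GeneratorConfig) -> list[tuple[str, str]]:
    """(broad, narrow) single-drug pairs where broad must dominate elementwise.

    A broader drug dominates a narrower one *by design* when it has a
    higher spectrum rank and the rule table gives both drugs the same
    intrinsic status for every organism: the two coverage events then share
    the latent threshold structure, so ordered thresholds (equivalently,
    ordered prevalence targets) force per-infection coverage monotonicity.
    Pairs with different organism ranges (e.g. a Gram-positive-only agent
    vs. a broad beta-lactam) are excluded — neither dominates elementwise
    no matter the targets.
    """
    status, _ = _organism_status(config)
    orgs = list(config.organism_mix)
    pairs = []
    drugs = [s for s in config.antibiotics if not s.is_combination]
    for a in drugs:
        for b in drugs:
            if a.spectrum_rank <= b.spectrum_rank:
                continue
            if all(status[o][a.name] == status[o][b.name] for o in orgs):
                pairs.append((a.name, b.name))
    return pairs


def _check_spectrum_consistency(
    config: GeneratorConfig, thresholds: dict[str, float], status: dict[str, dict[str, str]]
) -> None:
    for broad, narrow in dominance_pairs(config):
        if thresholds[broad] < thresholds[narrow] - 1e-12:
            raise InfeasiblePrevalenceError(
                f"narrower selection {narrow!r} (rank "
                f"{config.selection(narrow).spectrum_rank}) demands prevalence "
                f"{config.target_prevalence[narrow]} above what the dominating "
                f"broader selection {broad!r} allows "
                f"({config.target_prevalence[broad]})"
            )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_NOISE_CODES = [
    (f"DX_NOISE_{i}", "diagnosis") for i in range(10)
] + [
    (f"PROC_NOISE_{i}", "procedure") for i in range(6)
] + [
    (f"LAB_ORDER_{i}", "lab_order") for i in range(6)
] + [
    (f"MED_NOISE_{i}", "medication") for i in range(5)
] + [
    ("IMG_CHEST_XR", "imaging"), ("IMG_CT_ABD", "imaging"), ("RESP_O2", "respiratory"),
]

_SEXES = (["Female"] * 60 + ["Male"] * 40)
_RACES = ["White"] * 56 + ["Other"] * 20 + ["Asian"] * 14 + ["Black"] * 7 + ["Pacific Islander"] * 3
_ETHNICITIES = ["Non-Hispanic"] * 84 + ["Hispanic/Latino"] * 16
_INSURANCE = ["Medicare"] * 53 + ["Other"] * 43 + ["Medi-Cal"] * 4
_INSTITUTIONS = ["Academic ED"] * 90 + ["Community ED"] * 10
_CULTURE_TYPES = ["urine"] * 55 + ["blood"] * 30 + ["fluid"] * 12 + ["csf"] * 3


def _solve_censoring_intercept(z_std: np.ndarray, rate: float, slope: float) -> float:
    """Intercept of P(latent infection | negative culture) = expit(a + slope*z)."""
    if rate <= 0.0:
        return -np.inf
    if rate >= 1.0:
        return np.inf
    f = lambda a: expit(a + slope * z_std).mean() - rate
    return brentq(f, -30.0, 30.0, xtol=1e-10)


def _true_coverage_row(
    organisms: Sequence[str],
    z: float,
    thresholds: dict[str, float],
    status: dict[str, dict[str, str]],
    config: GeneratorConfig,
) -> dict[str, int]:
    """True coverage of every selection for one infection (AND over organisms, OR over components)."""
    out = {}
    for spec in config.antibiotics:
        covered_all = 1
        for org in organisms:
            org_cov = 0
            for drug in spec.components:
                st = status[org][drug]
                if st == "S" or (st == "free" and z <= thresholds[drug]):
                    org_cov = 1
                    break
            covered_all &= org_cov
        out[spec.name] = covered_all
    return out


def generate_cohort(config: GeneratorConfig) -> list[PatientInfection]:
    """Draw a synthetic cohort. Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    status, rules = _organism_status(config)

    # --- admission type -------------------------------------------------
    u = rng.random(n)
    negative = u < config.negative_culture_rate
    contaminant = (~negative) & (rng.random(n) < config.contaminant_rate)
    positive = ~negative & ~contaminant

    # --- covariates and latent resistance score ------------------------
    age = np.clip(rng.normal(68.0, 17.0, n), 18.0, 100.0)
    cov = {
        "prior_resistant_cultures": rng.poisson(0.3, n).astype(float),
        "prior_antibiotic_exposures": rng.poisson(0.8, n).astype(float),
        "comorbidity_count": rng.poisson(1.5, n).astype(float),
        "recent_hospitalization": (rng.random(n) < 0.2).astype(float),
        "age_centered_decades": (age - 68.0) / 10.0,
    }
    mu = np.zeros(n)
    for name, beta in config.covariate_effects.items():
        if name not in cov:
            raise ValueError(f"unknown covariate {name!r} in covariate_effects")
        mu += beta * cov[name]
    z = mu + config.noise_sd * rng.standard_normal(n)

    # --- organisms ------------------------------------------------------
    org_names = list(config.organism_mix)
    org_probs = np.array([config.organism_mix[o] for o in org_names])
    org_idx = rng.choice(len(org_names), size=n, p=org_probs)
    organisms = np.array(org_names, dtype=object)[org_idx]
    organisms[contaminant] = CONS
    second_org = np.where(
        positive & (rng.random(n) < config.polymicrobial_rate),
        np.array(org_names, dtype=object)[rng.choice(len(org_names), size=n, p=org_probs)],
        None,
    )

    # --- thresholds calibrated on retained positive infections ----------
    thresholds = _calibrate_thresholds(z[positive], organisms[positive], config)

    # --- latent infection status of negative-culture admissions ---------
    z_std = (z - z.mean()) / max(z.std(), 1e-12)
    n_neg = int(negative.sum())
    latent_infected = np.ones(n, dtype=bool)
    if n_neg:
        a = _solve_censoring_intercept(
            z_std[negative], config.latent_infection_rate_given_negative, config.censoring_strength
        )
        p_inf = expit(a + config.censoring_strength * z_std[negative])
        latent_infected[negative] = rng.random(n_neg) < p_inf

    # --- severity tier and clinician policy -----------------------------
    # clinicians see an imperfect severity proxy of the resistance score
    severity = z + 0.7 * rng.standard_normal(n)
    terciles = np.quantile(severity, [1 / 3, 2 / 3])
    tier = np.where(severity <= terciles[0], "low", np.where(severity <= terciles[1], "moderate", "high"))

    names = config.selection_names
    policy_cum = {}
    for t, weights in config.clinician_policy.items():
        unknown = set(weights) - set(names)
        if unknown:
            raise ValueError(f"clinician_policy[{t!r}] references unknown selections {sorted(unknown)}")
        w = np.array([weights.get(s, 0.0) for s in names], dtype=float)
        policy_cum[t] = w / w.sum()
    sel_idx = np.empty(n, dtype=int)
    for t, w in policy_cum.items():
        mask = tier == t
        sel_idx[mask] = rng.choice(len(names), size=int(mask.sum()), p=w)

    # --- timestamps ------------------------------------------------------
    y0, y1 = config.year_range
    years = rng.integers(y0, y1 + 1, size=n)
    day = rng.integers(0, 364, size=n)
    hour = rng.integers(0, 24, size=n)

    # --- assemble admissions --------------------------------------------
    cohort: list[PatientInfection] = []
    noise_codes = _NOISE_CODES
    for i in range(n):
        t0 = datetime(int(years[i]), 1, 1) + timedelta(days=int(day[i]), hours=int(hour[i]))
        organisms_i = [organisms[i]]
        if second_org[i] is not None:
            organisms_i.append(second_org[i])

        if positive[i] or contaminant[i]:
            cultures = [
                _draw_culture(rng, org, z[i], thresholds, status, config)
                for org in organisms_i
            ]
            infected = True
        else:
            cultures = [CultureResult(str(rng.choice(_CULTURE_TYPES)), NO_GROWTH, {})]
            infected = bool(latent_infected[i])

        truth_orgs = organisms_i if (positive[i] or contaminant[i]) else (organisms_i if infected else [])
        if truth_orgs:
            truth = _true_coverage_row(truth_orgs, z[i], thresholds, status, config)
        else:
            truth = {s: 1 for s in names}  # no infection: any selection "covers"

        selection = names[sel_idx[i]]
        admins, clin_sel, icd_flag, died = _draw_outcome_fields(
            rng, t0, selection, config, positive[i] or contaminant[i], infected
        )

        events: list[tuple[str, str, datetime]] = []
        numerics: list[tuple[str, float, datetime]] = []
        if config.include_events:
            events, numerics = _draw_events(
                rng, t0, cov, i, z_std[i], severity[i], icd_flag, noise_codes
            )

        cohort.append(
            PatientInfection(
                patient_id=f"P{i:06d}",
                infection_id=f"I{i:06d}",
                year=int(years[i]),
                prediction_time=t0,
                age_years=float(round(age[i], 1)),
                sex=str(rng.choice(_SEXES)),
                race=str(rng.choice(_RACES)),
                ethnicity=str(rng.choice(_ETHNICITIES)),
                insurance=str(rng.choice(_INSURANCE)),
                institution=str(rng.choice(_INSTITUTIONS)),
                coded_events=events,
                numeric_events=numerics,
                cultures=cultures,
                clinician_selection=clin_sel,
                antibiotics_administered=admins,
                infection_icd_flag=icd_flag,
                died_during_admission=died,
                latent_score=float(z[i]),
                latent_infected=infected,
                severity_tier=str(tier[i]),
                covariates={k: float(v[i]) for k, v in cov.items()},
                true_coverage=truth,
            )
        )
    return cohort


def _draw_culture(rng, organism, z_i, thresholds, status, config) -> CultureResult:
    calls: dict[str, str] = {}
    for drug in config.single_drugs:
        st = status[organism][drug]
        if st in {"R", "S"}:
            calls[drug] = "not_tested"  # lab does not test implausible pairs
            continue
        susceptible = z_i <= thresholds[drug]
        if rng.random() < config.missing_test_rate:
            calls[drug] = "not_tested"
        elif susceptible:
            calls[drug] = "S"
        else:
            calls[drug] = "I" if rng.random() < config.intermediate_call_rate else "R"
    ctype = "blood" if organism == CONS else str(rng.choice(_CULTURE_TYPES))
    return CultureResult(ctype, organism, calls)


def _sec(dt: datetime) -> datetime:
    """Timestamps at whole-second granularity (round-trips through CSV)."""
    return dt.replace(microsecond=0)


def _draw_outcome_fields(rng, t0, selection, config, culture_positive, infected):
    """Administrations, clinician selection, infection-ICD flag, death."""
    spec = config.selection(selection)
    if culture_positive:
        admins = [
            (drug, t0 + timedelta(hours=1), _sec(t0 + timedelta(days=float(2 + 3 * rng.random()))))
            for drug in spec.components
        ]
        return admins, selection, bool(rng.random() < 0.85), bool(rng.random() < 0.05)
    if infected:  # negative culture, latent infection: antibiotics usually continue
        if rng.random() < 0.9:
            admins = [
                (drug, t0 + timedelta(hours=2), _sec(t0 + timedelta(days=float(3 + 2 * rng.random()))))
                for drug in spec.components
            ]
        else:
            admins = [(spec.components[0], t0 + timedelta(hours=2), t0 + timedelta(hours=18))]
        return admins, (selection if admins else None), bool(rng.random() < 0.75), bool(rng.random() < 0.08)
    # negative culture, truly uninfected: antibiotics stopped early or never given
    r = rng.random()
    if r < 0.45:
        admins = []
        clin = None
    elif r < 0.9:
        admins = [(spec.components[0], t0 + timedelta(hours=2), _sec(t0 + timedelta(hours=float(6 + 12 * rng.random()))))]
        clin = selection
    else:  # a slice of uninfected patients still gets a full course (phenotype miss)
        admins = [(spec.components[0], t0 + timedelta(hours=2), t0 + timedelta(days=3))]
        clin = selection
    return admins, clin, bool(rng.random() < 0.08), bool(rng.random() < 0.01)


def _draw_events(rng, t0, cov, i, z_std_i, severity_i, icd_flag, noise_codes):
    events: list[tuple[str, str, datetime]] = []
    numerics: list[tuple[str, float, datetime]] = []
    days = lambda d: _sec(t0 - timedelta(days=float(d)))

    for k in range(int(cov["comorbidity_count"][i])):
        events.append((f"DX_COMORB_{k % 8}", "diagnosis", days(rng.uniform(10, 1800))))
    for k in range(int(cov["prior_antibiotic_exposures"][i])):
        back = rng.uniform(15, 330) if rng.random() < 0.7 else rng.uniform(380, 700)
        events.append((f"MED_ABX_{k % 4}", "medication", days(back)))
    for k in range(int(cov["prior_resistant_cultures"][i])):
        back = rng.uniform(20, 500)
        events.append(("MICRO_CULT_ORDER", "micro_order", days(back)))
        events.append(
            (f"SUSC|gram_negative_rod|ceftriaxone|R", "micro_order", days(back))
        )
    if cov["recent_hospitalization"][i]:
        events.append(("PROC_PRIOR_ADMIT", "procedure", days(rng.uniform(5, 180))))
    for _ in range(int(rng.poisson(3.0))):
        code, cat = noise_codes[int(rng.integers(len(noise_codes)))]
        back = rng.uniform(1, 1800) if cat == "diagnosis" else rng.uniform(1, 700)
        events.append((code, cat, days(back)))
    if icd_flag:
        # discharge coding lands after prediction time; must never leak into features
        events.append(("ICD_INF_PRIMARY", "diagnosis", t0 + timedelta(days=1)))

    for name, base, slope, sd, driver in (
        ("wbc", 8.0, 1.2, 1.5, z_std_i),
        ("creatinine", 1.0, 0.15, 0.3, z_std_i),
        ("temperature", 37.2, 0.25, 0.4, severity_i),
        ("heart_rate", 88.0, 4.0, 8.0, severity_i),
    ):
        for _ in range(int(rng.integers(1, 4))):
            numerics.append((name, float(base + slope * driver + sd * rng.standard_normal()), days(rng.uniform(0.05, 13.5))))
        if rng.random() < 0.3:  # stale measurement outside the 14-day window
            numerics.append((name, float(base + sd * rng.standard_normal()), days(rng.uniform(15, 30))))
    return events, numerics


# ---------------------------------------------------------------------------
# oracle probabilities
# ---------------------------------------------------------------------------

def analysis_set(cohort: Sequence[PatientInfection]) -> list[PatientInfection]:
    """Positive-culture infections retained after contaminant exclusion."""
    return [inf for inf in drop_contaminant_cultures(cohort) if inf.has_positive_culture]


def oracle_probabilities(
    config: GeneratorConfig, cohort: Sequence[PatientInfection]
) -> pd.DataFrame:
    """True conditional coverage probabilities P(covered | x, organism).

    Rows are the retained positive-culture infections, columns the
    configured selections. Conditions on the realized organism(s) and the
    covariate part of the latent score; only the latent noise is averaged
    over, so these are the Bayes-optimal predictions for the generative
    model and upper-bound any trained model's discrimination.

    Raises if the cohort is inconsistent with the config (e.g. generated
    under different parameters).
    """
    status, _ = _organism_status(config)
    retained = analysis_set(cohort)
    if not retained:
        raise ValueError("no retained positive-culture infections in cohort")
    z = np.array([inf.latent_score for inf in retained])
    orgs = np.array([inf.cultures[0].organism for inf in retained], dtype=object)
    thresholds = _calibrate_thresholds(z, orgs, config)

    mu = np.zeros(len(retained))
    for name, beta in config.covariate_effects.items():
        mu += beta * np.array([inf.covariates[name] for inf in retained])

    rows = {}
    for spec in config.antibiotics:
        p = np.ones(len(retained))
        for r, inf in enumerate(retained):
            # organisms share the infection's latent score, so the
            # conjunction over organisms binds at the smallest effective
            # threshold rather than multiplying marginal probabilities
            t_min = np.inf
            for culture in inf.cultures:
                org = culture.organism
                if org == NO_GROWTH or org in CONTAMINANT_ORGANISMS:
                    continue
                t_eff = -np.inf
                intrinsic_s = False
                for drug in spec.components:
                    st = status[org][drug]
                    if st == "S":
                        intrinsic_s = True
                        break
                    if st == "free":
                        t_eff = max(t_eff, thresholds[drug])
                if not intrinsic_s:
                    t_min = min(t_min, t_eff)
            if np.isposinf(t_min):
                p[r] = 1.0
            elif config.noise_sd == 0:
                p[r] = float(mu[r] <= t_min)
            else:
                p[r] = float(norm.cdf((t_min - mu[r]) / config.noise_sd))
        rows[spec.name] = p
    phi = pd.DataFrame(rows, index=[inf.infection_id for inf in retained])

    _verify_cohort_matches(config, retained, thresholds, status)
    return phi


def _verify_cohort_matches(config, retained, thresholds, status) -> None:
    """Spot-check that stored truth matches recomputed thresholds."""
    step = max(1, len(retained) // 64)
    for inf in retained[::step]:
        orgs = [c.organism for c in inf.cultures if c.organism != NO_GROWTH and c.organism not in CONTAMINANT_ORGANISMS]
        expect = _true_coverage_row(orgs, inf.latent_score, thresholds, status, config)
        if expect != inf.true_coverage:
            raise ValueError(
                "cohort is inconsistent with config: stored true coverage of "
                f"{inf.infection_id} does not match the recomputed generative model"
            )


def true_label_matrix(cohort: Sequence[PatientInfection]) -> pd.DataFrame:
    """Ground-truth coverage labels for every admission (generator's view)."""
    rows = [inf.true_coverage for inf in cohort]
    return pd.DataFrame(rows, index=[inf.infection_id for inf in cohort]).astype(float)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_ISO = "%Y-%m-%dT%H:%M:%S"


def write_cohort(cohort: Sequence[PatientInfection], outdir: str | Path, config: GeneratorConfig | None = None) -> dict[str, str]:
    """Write one wide CSV per entity plus a manifest; returns path -> sha256."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inf_rows, event_rows, num_rows, cult_rows, admin_rows, truth_rows = [], [], [], [], [], []
    for p in cohort:
        inf_rows.append({
            "infection_id": p.infection_id, "patient_id": p.patient_id, "year": p.year,
            "prediction_time": p.prediction_time.strftime(_ISO), "age_years": p.age_years,
            "sex": p.sex, "race": p.race, "ethnicity": p.ethnicity, "insurance": p.insurance,
            "institution": p.institution, "clinician_selection": p.clinician_selection or "",
            "infection_icd_flag": int(p.infection_icd_flag),
            "died_during_admission": int(p.died_during_admission),
        })
        for code, cat, ts in p.coded_events:
            event_rows.append({"infection_id": p.infection_id, "code": code, "category": cat,
                               "timestamp": ts.strftime(_ISO)})
        for name, val, ts in p.numeric_events:
            num_rows.append({"infection_id": p.infection_id, "measurement": name,
                             "value": round(val, 6), "timestamp": ts.strftime(_ISO)})
        for c in p.cultures:
            if c.organism == NO_GROWTH:
                cult_rows.append({"infection_id": p.infection_id, "culture_type": c.culture_type,
                                  "organism": c.organism, "antibiotic": "", "call": ""})
            else:
                for drug, call in c.susceptibilities.items():
                    cult_rows.append({"infection_id": p.infection_id, "culture_type": c.culture_type,
                                      "organism": c.organism, "antibiotic": drug, "call": call})
        for drug, start, stop in p.antibiotics_administered:
            admin_rows.append({"infection_id": p.infection_id, "drug": drug,
                               "start": start.strftime(_ISO), "stop": stop.strftime(_ISO)})
        truth_rows.append({"infection_id": p.infection_id, "latent_score": round(p.latent_score, 9),
                           "latent_infected": int(p.latent_infected), "severity_tier": p.severity_tier,
                           **{f"cov_{k}": v for k, v in p.covariates.items()},
                           **{f"true::{k}": v for k, v in p.true_coverage.items()}})
    files = {
        "infections.csv": pd.DataFrame(inf_rows),
        "coded_events.csv": pd.DataFrame(event_rows, columns=["infection_id", "code", "category", "timestamp"]),
        "numeric_events.csv": pd.DataFrame(num_rows, columns=["infection_id", "measurement", "value", "timestamp"]),
        "cultures.csv": pd.DataFrame(cult_rows),
        "administrations.csv": pd.DataFrame(admin_rows, columns=["infection_id", "drug", "start", "stop"]),
        "truth.csv": pd.DataFrame(truth_rows),
    }
    hashes = {}
    for name, df in files.items():
        path = outdir / name
        df.to_csv(path, index=False)
        hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {"n_patients": len(cohort), "files": hashes}
    if config is not None:
        manifest["seed"] = config.seed
        manifest["config"] = config.to_dict()
    (outdir / "cohort_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return hashes


def read_cohort(outdir: str | Path) -> list[PatientInfection]:
    """Reconstruct a cohort from :func:`write_cohort` output."""
    outdir = Path(outdir)
    inf = pd.read_csv(outdir / "infections.csv", keep_default_na=False)
    events = pd.read_csv(outdir / "coded_events.csv")
    nums = pd.read_csv(outdir / "numeric_events.csv")
    cults = pd.read_csv(outdir / "cultures.csv", keep_default_na=False)
    admins = pd.read_csv(outdir / "administrations.csv")
    truth = pd.read_csv(outdir / "truth.csv").set_index("infection_id")

    ev_by = {k: v for k, v in events.groupby("infection_id")} if len(events) else {}
    num_by = {k: v for k, v in nums.groupby("infection_id")} if len(nums) else {}
    cult_by = {k: v for k, v in cults.groupby("infection_id")}
    adm_by = {k: v for k, v in admins.groupby("infection_id")} if len(admins) else {}

    parse = lambda s: datetime.strptime(s, _ISO)
    cohort = []
    for row in inf.itertuples(index=False):
        iid = row.infection_id
        cultures = []
        for (ctype, org), grp in cult_by.get(iid, pd.DataFrame()).groupby(["culture_type", "organism"], sort=False):
            if org == NO_GROWTH:
                cultures.append(CultureResult(ctype, org, {}))
            else:
                cultures.append(CultureResult(ctype, org, dict(zip(grp["antibiotic"], grp["call"]))))
        trow = truth.loc[iid]
        cov = {k[len("cov_"):]: float(v) for k, v in trow.items() if str(k).startswith("cov_")}
        true_cov = {k[len("true::"):]: int(v) for k, v in trow.items() if str(k).startswith("true::")}
        cohort.append(PatientInfection(
            patient_id=row.patient_id, infection_id=iid, year=int(row.year),
            prediction_time=parse(row.prediction_time), age_years=float(row.age_years),
            sex=row.sex, race=row.race, ethnicity=row.ethnicity, insurance=row.insurance,
            institution=row.institution,
            coded_events=[(e.code, e.category, parse(e.timestamp)) for e in ev_by.get(iid, pd.DataFrame()).itertuples(index=False)] if iid in ev_by else [],
            numeric_events=[(m.measurement, float(m.value), parse(m.timestamp)) for m in num_by.get(iid, pd.DataFrame()).itertuples(index=False)] if iid in num_by else [],
            cultures=cultures,
            clinician_selection=row.clinician_selection or None,
            antibiotics_administered=[(a.drug, parse(a.start), parse(a.stop)) for a in adm_by.get(iid, pd.DataFrame()).itertuples(index=False)] if iid in adm_by else [],
            infection_icd_flag=bool(row.infection_icd_flag),
            died_during_admission=bool(row.died_during_admission),
            latent_score=float(trow["latent_score"]),
            latent_infected=bool(trow["latent_infected"]),
            severity_tier=str(trow["severity_tier"]),
            covariates=cov,
            true_coverage=true_cov,
        ))
    return cohort
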