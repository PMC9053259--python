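"""Coverage labels from culture susceptibility reports.

An antibiotic selection *covers* an infection when every organism that grew
in the patient's cultures is susceptible (``S`` — not intermediate, not
resistant) to at least one drug in the selection. Microbiology labs only
test drug/organism pairs that could plausibly be active, so many calls are
missing and must be imputed from microbiological knowledge: intrinsic
resistance (e.g. Gram-negative rods to vancomycin), intrinsic
susceptibility (e.g. *Streptococcus agalactiae* to cephalosporins), and
within-class inference across cephalosporin generations. Calls that no rule
resolves stay missing and exclude the infection from that selection's rows.

Cultures growing only Coagulase-negative Staphylococci are treated as
contaminants and removed from the positive-culture analysis set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import PatientInfection, SelectionSpec

logger = logging.getLogger(__name__)

NO_GROWTH = "no growth"
#: Organisms treated as probable culture contaminants.
CONTAMINANT_ORGANISMS = frozenset({"Coagulase-negative Staphylococci"})

VALID_CALLS = {"S", "I", "R", "not_tested"}


class RuleConflictError(ValueError):
    """Two imputation rules fire with contradictory results."""


@dataclass
class ImputationRuleTable:
    """Microbiological rules for imputing untested susceptibility calls.

    Parameters
    ----------
    intrinsic_resistance : list of (target, antibiotic)
        ``target`` is an organism name or ``"group:<name>"``.
    intrinsic_susceptibility : list of (target, class_name)
        Class names index into ``class_hierarchy``.
    class_hierarchy : mapping class -> list of {generation, members}
        Generations must be strictly increasing integers; susceptibility to
        an earlier generation implies susceptibility to later generations.
    groups : mapping group name -> list of member organisms
    """

    intrinsic_resistance: list[tuple[str, str]] = field(default_factory=list)
    intrinsic_susceptibility: list[tuple[str, str]] = field(default_factory=list)
    class_hierarchy: dict[str, list[dict]] = field(default_factory=dict)
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    def groups_of(self, organism: str) -> set[str]:
        return {g for g, members in self.groups.items() if organism in members}

    def _matches(self, target: str, organism: str) -> bool:
        if target.startswith("group:"):
            return target[len("group:"):] in self.groups_of(organism)
        return target == organism

    def class_of(self, antibiotic: str) -> tuple[str, int] | None:
        """Return (class name, generation) for a classed antibiotic."""
        for cls, tiers in self.class_hierarchy.items():
            for tier in tiers:
                if antibiotic in tier["members"]:
                    return cls, int(tier["generation"])
        return None

    def class_members(self, cls: str) -> list[str]:
        return [m for tier in self.class_hierarchy.get(cls, []) for m in tier["members"]]

    def is_intrinsically_resistant(self, organism: str, antibiotic: str) -> bool:
        return any(
            abx == antibiotic and self._matches(target, organism)
            for target, abx in self.intrinsic_resistance
        )

    def is_intrinsically_susceptible(self, organism: str, antibiotic: str) -> bool:
        for target, cls in self.intrinsic_susceptibility:
            if antibiotic in self.class_members(cls) and self._matches(target, organism):
                return True
        return False

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for cls, tiers in self.class_hierarchy.items():
            gens = [int(t["generation"]) for t in tiers]
            if sorted(set(gens)) != gens:
                raise ValueError(
                    f"class hierarchy for {cls!r} must have strictly "
                    f"increasing generations, got {gens}"
                )
        organisms = {o for members in self.groups.values() for o in members}
        organisms |= {t for t, _ in self.intrinsic_resistance if not t.startswith("group:")}
        organisms |= {t for t, _ in self.intrinsic_susceptibility if not t.startswith("group:")}
        for org in organisms:
            for target, abx in self.intrinsic_resistance:
                if self._matches(target, org) and self.is_intrinsically_susceptible(org, abx):
                    raise RuleConflictError(
                        f"({org}, {abx}) appears intrinsically resistant via "
                        f"{(target, abx)} and intrinsically susceptible via a "
                        "class rule"
                    )

    # -- IO ----------------------------------------------------------------
    @classmethod
    def from_dict(cls, raw: Mapping) -> "ImputationRuleTable":
        return cls(
            intrinsic_resistance=[tuple(p) for p in raw.get("intrinsic_resistance", [])],
            intrinsic_susceptibility=[tuple(p) for p in raw.get("intrinsic_susceptibility", [])],
            class_hierarchy=dict(raw.get("antibiotic_classes", {})),
            groups=dict(raw.get("groups", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ImputationRuleTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "groups": self.groups,
            "antibiotic_classes": self.class_hierarchy,
            "intrinsic_resistance": [list(p) for p in self.intrinsic_resistance],
            "intrinsic_susceptibility": [list(p) for p in self.intrinsic_susceptibility],
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def default_rule_table() -> ImputationRuleTable:
    """The rule table shipped with the package."""
    text = resources.files("pabgram").joinpath("data/default_rules.yaml").read_text()
    return ImputationRuleTable.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def drop_contaminant_cultures(
    cohort: Sequence["PatientInfection"],
    contaminants: frozenset[str] = CONTAMINANT_ORGANISMS,
) -> list["PatientInfection"]:
    """Remove infections whose only growth is a contaminant organism.

    Infections with additional true growth are retained (the contaminant
    isolates are simply ignored downstream). Negative-culture admissions
    pass through untouched; they are handled by the bucket logic of the
    sensitivity analysis, not here.
    """
    kept: list[PatientInfection] = []
    n_dropped = 0
    for inf in cohort:
        grown = [c.organism for c in inf.cultures if c.organism != NO_GROWTH]
        if grown and all(org in contaminants for org in grown):
            n_dropped += 1
            continue
        kept.append(inf)
    logger.info("drop_contaminant_cultures: removed %d contaminant-only infections", n_dropped)
    return kept


def impute_call(
    organism: str,
    antibiotic: str,
    observed_calls: Mapping[str, str],
    rules: ImputationRuleTable,
) -> str:
    """Impute a missing susceptibility call. Returns ``'S'``, ``'R'`` or ``'missing'``.

    Rules fire in priority order: intrinsic resistance, intrinsic
    susceptibility, then within-class inference (susceptible to an earlier
    cephalosporin generation implies susceptible to later ones, and — the
    contrapositive — non-susceptible to a later generation implies
    non-susceptible to earlier ones).
    """
    if rules.is_intrinsically_resistant(organism, antibiotic):
        return "R"
    if rules.is_intrinsically_susceptible(organism, antibiotic):
        return "S"
    classed = rules.class_of(antibiotic)
    if classed is not None:
        cls, gen = classed
        inferred_s = inferred_r = None
        for other in rules.class_members(cls):
            call = observed_calls.get(other)
            if call not in {"S", "I", "R"}:
                continue
            _, other_gen = rules.class_of(other)  # type: ignore[misc]
            if call == "S" and other_gen <= gen:
                inferred_s = other
            elif call in {"I", "R"} and other_gen >= gen:
                inferred_r = other
        if inferred_s and inferred_r:
            raise RuleConflictError(
                f"class inference for ({organism}, {antibiotic}) conflicts: "
                f"susceptible via {inferred_s}, non-susceptible via {inferred_r}"
            )
        if inferred_s:
            return "S"
        if inferred_r:
            return "R"
    return "missing"


def _resolve_call(
    organism: str,
    antibiotic: str,
    observed_calls: Mapping[str, str],
    rules: ImputationRuleTable,
) -> tuple[str, bool]:
    """Return (call, was_imputed) with call in {S, I, R, missing}."""
    call = observed_calls.get(antibiotic, "not_tested")
    if call in {"S", "I", "R"}:
        return call, False
    return impute_call(organism, antibiotic, observed_calls, rules), True


def coverage_label(
    infection: "PatientInfection",
    selection: "SelectionSpec",
    rules: ImputationRuleTable,
    contaminants: frozenset[str] = CONTAMINANT_ORGANISMS,
) -> tuple[float, str]:
    """Label one (infection, selection) cell.

    Returns ``(label, provenance)`` where label is 1.0, 0.0 or NaN and
    provenance is ``'observed'``, ``'imputed'`` or ``''`` (missing).

    The selection covers the infection iff every retained organism is
    susceptible to at least one component drug; intermediate counts as not
    susceptible. Three-valued logic propagates residual missingness only
    when it could change the outcome.
    """
    isolates = [
        c for c in infection.cultures
        if c.organism != NO_GROWTH and c.organism not in contaminants
    ]
    if not isolates:
        raise ValueError(f"infection {infection.infection_id} has no retained positive isolate")
    label = 1.0
    any_imputed = False
    for iso in isolates:
        org_covered: float = 0.0  # three-valued OR over component drugs
        org_unknown = False
        for drug in selection.components:
            call, imputed = _resolve_call(iso.organism, drug, iso.susceptibilities, rules)
            if call == "S":
                org_covered = 1.0
                any_imputed |= imputed
                break
            if call == "missing":
                org_unknown = True
            else:
                any_imputed |= imputed
        if org_covered != 1.0:
            if org_unknown:
                label = np.nan if label == 1.0 else label
            else:
                label = 0.0
                break  # conjunction fails regardless of other organisms
    if np.isnan(label):
        return np.nan, ""
    return label, "imputed" if any_imputed else "observed"


@dataclass
class SusceptibilityLabelMatrix:
    """N x M coverage labels with per-cell provenance.

    ``labels`` holds 1.0 (covered), 0.0 (not covered) or NaN (missing after
    imputation); ``provenance`` holds 'observed', 'imputed',
    'phenotype_positive' or '' for missing cells. Rows are infection ids,
    columns selection names.
    """

    labels: pd.DataFrame
    provenance: pd.DataFrame

    @property
    def selections(self) -> list[str]:
        return list(self.labels.columns)

    def prevalence(self) -> pd.Series:
        """Per-selection covered fraction among non-missing cells."""
        return self.labels.mean(axis=0, skipna=True)

    def to_csv(self, labels_path: str | Path, provenance_path: str | Path) -> None:
        self.labels.to_csv(labels_path, index_label="infection_id")
        self.provenance.to_csv(provenance_path, index_label="infection_id")

    @classmethod
    def from_csv(cls, labels_path: str | Path, provenance_path: str | Path) -> "SusceptibilityLabelMatrix":
        labels = pd.read_csv(labels_path, index_col="infection_id")
        prov = pd.read_csv(provenance_path, index_col="infection_id", keep_default_na=False)
        return cls(labels=labels, provenance=prov)


def build_label_matrix(
    cohort: Iterable["PatientInfection"],
    selections: Sequence["SelectionSpec"],
    rules: ImputationRuleTable | None = None,
) -> SusceptibilityLabelMatrix:
    """Apply :func:`coverage_label` to every (infection, selection) cell.

    The cohort should already have contaminant-only cultures removed; pass
    the output of :func:`drop_contaminant_cultures`.
    """
    rules = rules if rules is not None else default_rule_table()
    names = [s.name for s in selections]
    if len(set(names)) != len(names):
        raise ValueError("duplicate selection names")
    rows, lab_rows, prov_rows = [], [], []
    for inf in cohort:
        rows.append(inf.infection_id)
        lab, prov = [], []
        for sel in selections:
            value, why = coverage_label(inf, sel, rules)
            lab.append(value)
            prov.append(why)
        lab_rows.append(lab)
        prov_rows.append(prov)
    labels = pd.DataFrame(lab_rows, index=rows, columns=names, dtype=float)
    provenance = pd.DataFrame(prov_rows, index=rows, columns=names)
    return SusceptibilityLabelMatrix(labels=labels, provenance=provenance)
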