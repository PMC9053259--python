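"""Budget-constrained antibiotic allocation.

Given predicted coverage probabilities Φ (N admissions × M selections) and
a budget vector K saying how many times each selection must be used, find
the binary assignment S maximizing Σ φ_ij s_ij subject to each admission
receiving exactly one selection (row sums 1) and each selection being used
exactly K_j times (column sums K_j). This is a transportation problem with
unit row supplies, so an integral optimum always exists; it is solved
exactly by expanding each selection column into K_j identical copies and
running the rectangular Hungarian assignment algorithm. A deterministic
lexicographic perturbation (+j·1e-9 on column j) fixes tie-breaking; the
reported objective is computed on the unperturbed Φ.

Budget sweeps re-solve the problem while exchanging broad-spectrum budget
for a narrower selection one prescription at a time, tracing the
coverage-vs-stewardship trade-off curve against clinician and random
baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cohort import PatientInfection


@dataclass
class AllocationProblem:
    """One instance of the budget-constrained assignment."""

    phi: np.ndarray  # N x M predicted coverage probabilities
    budgets: np.ndarray  # length M, integer, sums to N
    selections: list[str]

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.budgets = np.asarray(self.budgets)
        n, m = self.phi.shape
        if len(self.budgets) != m or len(self.selections) != m:
            raise ValueError("budgets/selections length must match phi columns")
        if np.any(self.budgets < 0):
            raise ValueError("negative budget")
        if not np.issubdtype(self.budgets.dtype, np.integer):
            if not np.allclose(self.budgets, np.round(self.budgets)):
                raise ValueError("budgets must be integers")
            self.budgets = np.round(self.budgets).astype(int)
        if int(self.budgets.sum()) != n:
            raise ValueError(
                f"infeasible: budgets sum to {int(self.budgets.sum())} but N={n}"
            )
        if np.any(self.phi < -1e-12) or np.any(self.phi > 1 + 1e-12):
            raise ValueError("phi entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.phi.shape[0]

    @property
    def m(self) -> int:
        return self.phi.shape[1]


@dataclass
class Allocation:
    """A feasible assignment: column index per admission."""

    assignment: np.ndarray  # length N, values in 0..M-1
    objective: float
    selections: list[str]
    status: str = "optimal"

    @property
    def matrix(self) -> np.ndarray:
        """Binary N x M matrix form of the assignment."""
        S = np.zeros((len(self.assignment), len(self.selections)), dtype=int)
        S[np.arange(len(self.assignment)), self.assignment] = 1
        return S

    def column_counts(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=len(self.selections))


def solve_allocation(problem: AllocationProblem) -> Allocation:
    """Maximize total predicted coverage subject to the budgets. Exact and integral."""
    phi = problem.phi + np.arange(problem.m) * 1e-9  # deterministic tie-break
    col_of_slot = np.repeat(np.arange(problem.m), problem.budgets)
    cost = -phi[:, col_of_slot]  # N x N expanded assignment problem
    rows, slots = linear_sum_assignment(cost)
    assignment = np.empty(problem.n, dtype=int)
    assignment[rows] = col_of_slot[slots]
    objective = float(problem.phi[np.arange(problem.n), assignment].sum())
    return Allocation(assignment=assignment, objective=objective,
                      selections=list(problem.selections))


def brute_force_allocation(problem: AllocationProblem) -> Allocation:
    """Exhaustive enumeration over all budget-feasible assignments.

    Independent oracle for small instances (M^N candidates); used to verify
    the solver, never as the solver.
    """
    from itertools import product

    best_obj, best_assign = -np.inf, None
    for cand in product(range(problem.m), repeat=problem.n):
        counts = np.bincount(cand, minlength=problem.m)
        if not np.array_equal(counts, problem.budgets):
            continue
        obj = float(problem.phi[np.arange(problem.n), cand].sum())
        if obj > best_obj:
            best_obj, best_assign = obj, np.array(cand)
    if best_assign is None:
        raise ValueError("no feasible assignment")
    return Allocation(assignment=best_assign, objective=best_obj,
                      selections=list(problem.selections), status="enumerated")


def coverage_rate(allocation: Allocation, labels: pd.DataFrame | np.ndarray) -> float:
    """Fraction of admissions whose assigned selection truly covers them."""
    lab = labels.to_numpy(dtype=float) if isinstance(labels, pd.DataFrame) else np.asarray(labels, dtype=float)
    assigned = lab[np.arange(len(allocation.assignment)), allocation.assignment]
    bad = np.flatnonzero(np.isnan(assigned))
    if len(bad):
        raise ValueError(f"missing label in assigned cells at rows {bad[:20].tolist()}")
    return float(assigned.mean())


def clinician_budgets(
    cohort: list[PatientInfection] | pd.Series, selections: list[str]
) -> np.ndarray:
    """K_j = number of admissions whose clinician selection was j."""
    if isinstance(cohort, pd.Series):
        chosen = cohort
    else:
        chosen = pd.Series([inf.clinician_selection for inf in cohort])
    unknown = set(chosen.dropna()) - set(selections)
    if unknown or chosen.isna().any():
        raise ValueError(
            f"admissions with selections outside the modelled set: {sorted(map(str, unknown))}"
            + (" (and admissions without a selection)" if chosen.isna().any() else "")
        )
    counts = chosen.value_counts()
    return np.array([int(counts.get(s, 0)) for s in selections])


def clinician_allocation(clinician_selections: pd.Series, selections: list[str]) -> Allocation:
    """The allocation clinicians actually made (objective undefined, set to NaN)."""
    index = {s: j for j, s in enumerate(selections)}
    assignment = np.array([index[s] for s in clinician_selections])
    return Allocation(assignment=assignment, objective=float("nan"),
                      selections=list(selections), status="clinician")


def random_allocation(budgets: np.ndarray, seed: int, selections: list[str] | None = None) -> Allocation:
    """Uniform random permutation of the budget multiset across admissions."""
    budgets = np.asarray(budgets, dtype=int)
    pool = np.repeat(np.arange(len(budgets)), budgets)
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(pool)
    names = selections if selections is not None else [f"sel{j}" for j in range(len(budgets))]
    return Allocation(assignment=assignment, objective=float("nan"),
                      selections=list(names), status="random")


@dataclass
class SweepResult:
    """Broad→narrow budget sweep: one coverage curve plus crossing points."""

    broad: str
    narrow: str
    curve: pd.DataFrame  # columns: k, percent_narrowed, coverage, objective
    max_k_at_clinician_rate: int | None
    max_k_at_random_rate: int | None
    clinician_rate: float
    random_rate: float

    @property
    def percent_narrowed_at_clinician_rate(self) -> float | None:
        if self.max_k_at_clinician_rate is None:
            return None
        k_broad = int(self.curve["k"].max())
        return 100.0 * self.max_k_at_clinician_rate / k_broad if k_broad else 0.0


def budget_sweep(
    problem: AllocationProblem,
    labels: pd.DataFrame | np.ndarray,
    pair: tuple[str, str],
    clinician_rate: float,
    random_rate: float,
    step: int = 1,
) -> SweepResult:
    """Exchange broad-selection budget for the narrow selection, k at a time.

    ``pair = (broad, narrow)`` must be ordered by antibiogram value; at each
    k the problem is re-solved with K'_broad = K_broad − k and
    K'_narrow = K_narrow + k, and the realized coverage recorded. The
    crossing points report the largest k whose coverage still matches the
    clinician and random baselines.
    """
    broad, narrow = pair
    try:
        jb = problem.selections.index(broad)
        jn = problem.selections.index(narrow)
    except ValueError as err:
        raise ValueError(f"sweep pair {pair} not among problem selections") from err
    k_broad = int(problem.budgets[jb])
    ks = list(range(0, k_broad + 1, step))
    if ks[-1] != k_broad:
        ks.append(k_broad)
    records = []
    for k in ks:
        budgets = problem.budgets.copy()
        budgets[jb] -= k
        budgets[jn] += k
        sub = AllocationProblem(phi=problem.phi, budgets=budgets, selections=problem.selections)
        alloc = solve_allocation(sub)
        records.append({
            "k": k,
            "percent_narrowed": 100.0 * k / k_broad if k_broad else 0.0,
            "coverage": coverage_rate(alloc, labels),
            "objective": alloc.objective,
        })
    curve = pd.DataFrame(records)
    at_or_above = lambda rate: (
        int(curve.loc[curve["coverage"] >= rate, "k"].max())
        if (curve["coverage"] >= rate).any() else None
    )
    return SweepResult(
        broad=broad, narrow=narrow, curve=curve,
        max_k_at_clinician_rate=at_or_above(clinician_rate),
        max_k_at_random_rate=at_or_above(random_rate),
        clinician_rate=clinician_rate, random_rate=random_rate,
    )
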