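"""Budget-constrained allocation: solver exactness, feasibility, sweeps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pabgram.allocation import (
    Allocation,
    AllocationProblem,
    brute_force_allocation,
    budget_sweep,
    clinician_allocation,
    clinician_budgets,
    coverage_rate,
    random_allocation,
    solve_allocation,
)

from conftest import assert_feasible


def _random_problem(rng, n=None, m=None):
    n = n if n is not None else int(rng.integers(2, 9))
    m = m if m is not None else int(rng.integers(1, 5))
    phi = rng.random((n, m))
    cuts = np.sort(rng.integers(0, n + 1, size=m - 1))
    budgets = np.diff(np.concatenate(([0], cuts, [n])))
    return AllocationProblem(phi=phi, budgets=budgets, selections=[f"s{j}" for j in range(m)])


class TestSolver:
    def test_two_by_two_hand_example(self):
        # the only competing feasible assignment scores 0.2 + 0.8 = 1.0
        problem = AllocationProblem(
            phi=np.array([[0.9, 0.2], [0.8, 0.7]]), budgets=np.array([1, 1]),
            selections=["a", "b"],
        )
        alloc = solve_allocation(problem)
        assert alloc.assignment.tolist() == [0, 1]
        assert alloc.objective == pytest.approx(1.6)
        assert_feasible(alloc, problem.budgets)

    def test_single_column_forced(self):
        phi = np.array([[0.3], [0.9], [0.1]])
        problem = AllocationProblem(phi=phi, budgets=np.array([3]), selections=["only"])
        alloc = solve_allocation(problem)
        assert alloc.assignment.tolist() == [0, 0, 0]
        assert alloc.objective == pytest.approx(phi.sum())

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            problem = _random_problem(rng)
            exact = brute_force_allocation(problem)
            solved = solve_allocation(problem)
            assert solved.objective == pytest.approx(exact.objective, abs=1e-9)
            assert_feasible(solved, problem.budgets)

    def test_objective_invariant_to_row_permutation(self):
        rng = np.random.default_rng(1)
        problem = _random_problem(rng, n=7, m=3)
        perm = rng.permutation(7)
        permuted = AllocationProblem(
            phi=problem.phi[perm], budgets=problem.budgets, selections=problem.selections
        )
        assert solve_allocation(problem).objective == pytest.approx(
            solve_allocation(permuted).objective
        )

    def test_budget_sum_mismatch_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            AllocationProblem(phi=np.ones((3, 2)) * 0.5, budgets=np.array([1, 1]),
                              selections=["a", "b"])

    def test_negative_budget_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            AllocationProblem(phi=np.ones((2, 2)) * 0.5, budgets=np.array([3, -1]),
                              selections=["a", "b"])


class TestCoverageRate:
    def test_all_covered_and_none_covered(self):
        alloc = Allocation(assignment=np.array([0, 1, 0]), objective=0.0,
                           selections=["a", "b"])
        assert coverage_rate(alloc, np.ones((3, 2))) == 1.0
        assert coverage_rate(alloc, np.zeros((3, 2))) == 0.0

    def test_missing_assigned_label_raises_with_rows(self):
        labels = np.array([[1.0, np.nan], [np.nan, 1.0]])
        alloc = Allocation(assignment=np.array([1, 1]), objective=0.0,
                           selections=["a", "b"])
        with pytest.raises(ValueError, match=r"\[0\]"):
            coverage_rate(alloc, labels)

    def test_clinician_coverage_matches_direct_tabulation(self, small_cohort, small_config):
        from pabgram.cohort import analysis_set, true_label_matrix

        retained = analysis_set(small_cohort)
        truth = true_label_matrix(retained)
        selections = list(truth.columns)
        chosen = pd.Series([inf.clinician_selection for inf in retained], index=truth.index)
        alloc = clinician_allocation(chosen, selections)
        expected = np.mean([truth.loc[i, s] for i, s in chosen.items()])
        assert coverage_rate(alloc, truth) == pytest.approx(expected)


class TestBudgets:
    def test_all_one_selection(self):
        chosen = pd.Series(["a"] * 5)
        assert clinician_budgets(chosen, ["a", "b"]).tolist() == [5, 0]

    def test_permutation_invariance(self, small_cohort, small_config):
        from pabgram.cohort import analysis_set

        retained = analysis_set(small_cohort)
        sels = small_config.selection_names
        k1 = clinician_budgets(retained, sels)
        k2 = clinician_budgets(list(reversed(retained)), sels)
        assert np.array_equal(k1, k2)
        assert k1.sum() == len(retained)

    def test_selection_outside_modelled_set_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            clinician_budgets(pd.Series(["a", "zzz"]), ["a", "b"])

    def test_budgets_match_policy_frequencies(self, small_cohort, small_config):
        from pabgram.cohort import analysis_set

        retained = analysis_set(small_cohort)
        k = clinician_budgets(retained, small_config.selection_names)
        # every configured policy selection should appear with plausible mass
        tiers = small_config.clinician_policy.values()
        avg_w = {
            s: np.mean([w.get(s, 0.0) for w in tiers]) for s in small_config.selection_names
        }
        for s, kk in zip(small_config.selection_names, k):
            assert abs(kk / len(retained) - avg_w[s]) < 0.12, s


class TestRandomAllocation:
    def test_expected_coverage_analytic(self):
        rng = np.random.default_rng(0)
        n, m = 60, 3
        labels = (rng.random((n, m)) < [0.3, 0.6, 0.9]).astype(float)
        budgets = np.array([20, 20, 20])
        expected = sum(
            budgets[j] / n * labels[:, j].mean() for j in range(m)
        )
        draws = [
            coverage_rate(random_allocation(budgets, seed=s), labels) for s in range(2000)
        ]
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - expected) < 3 * se + 1e-9

    def test_concentrated_budget_is_the_unique_feasible_point(self):
        budgets = np.array([0, 4, 0])
        alloc = random_allocation(budgets, seed=1)
        assert alloc.assignment.tolist() == [1, 1, 1, 1]
        assert_feasible(alloc, budgets)

    def test_two_seeds_differ(self):
        budgets = np.array([5, 5])
        a = random_allocation(budgets, seed=1).assignment
        b = random_allocation(budgets, seed=2).assignment
        assert not np.array_equal(a, b)


class TestBudgetSweep:
    def _setup(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        phi = rng.random((n, 2))
        phi[:, 0] = np.maximum(phi[:, 0], phi[:, 1])  # broad dominates narrow
        labels = (rng.random((n, 2)) < phi).astype(float)
        budgets = np.array([n // 2, n - n // 2])
        problem = AllocationProblem(phi=phi, budgets=budgets, selections=["broad", "narrow"])
        return problem, labels

    def test_k_zero_reproduces_base_allocation(self):
        problem, labels = self._setup()
        base = solve_allocation(problem)
        res = budget_sweep(problem, labels, ("broad", "narrow"),
                           clinician_rate=0.5, random_rate=0.4)
        assert res.curve.loc[0, "k"] == 0
        assert res.curve.loc[0, "objective"] == pytest.approx(base.objective)
        assert res.curve.loc[0, "coverage"] == pytest.approx(coverage_rate(base, labels))

    def test_identical_columns_coverage_constant(self):
        rng = np.random.default_rng(3)
        phi_col = rng.random(20)
        phi = np.column_stack([phi_col, phi_col])
        labels_col = (rng.random(20) < phi_col).astype(float)
        labels = np.column_stack([labels_col, labels_col])
        problem = AllocationProblem(phi=phi, budgets=np.array([10, 10]),
                                    selections=["broad", "narrow"])
        res = budget_sweep(problem, labels, ("broad", "narrow"), 0.5, 0.4)
        assert res.curve["coverage"].nunique() == 1

    def test_dominating_broad_objective_non_increasing(self):
        problem, labels = self._setup(seed=5)
        res = budget_sweep(problem, labels, ("broad", "narrow"), 0.5, 0.4)
        diffs = np.diff(res.curve["objective"].to_numpy())
        assert (diffs <= 1e-9).all()

    def test_unknown_pair_rejected(self):
        problem, labels = self._setup()
        with pytest.raises(ValueError, match="not among"):
            budget_sweep(problem, labels, ("broad", "nope"), 0.5, 0.4)

    def test_crossing_points_consistent_with_curve(self):
        problem, labels = self._setup(seed=9, n=40)
        res = budget_sweep(problem, labels, ("broad", "narrow"),
                           clinician_rate=0.55, random_rate=0.30)
        cv = res.curve.set_index("k")["coverage"]
        if res.max_k_at_clinician_rate is not None:
            assert cv[res.max_k_at_clinician_rate] >= 0.55
            later = cv[cv.index > res.max_k_at_clinician_rate]
            assert (later < 0.55).all()


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_solver_feasible_on_random_seeds(seed):
    rng = np.random.default_rng(seed)
    problem = _random_problem(rng)
    alloc = solve_allocation(problem)
    assert_feasible(alloc, problem.budgets)
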