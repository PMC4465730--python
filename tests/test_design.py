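"""Attribute balance, information matrix, D-criterion and coordinate exchange."""
from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from scipy.special import expit

import paypref as pp
from paypref.design import (
    DesignError,
    _difference_matrix,
    bayesian_d_criterion,
    dominance_check,
    mnl_information_matrix,
    plan_attribute_balance,
    random_feasible_design,
)
from paypref.priors import PriorSpec, sample_prior
from paypref.schema import ChoiceSet, effects_code

from conftest import make_schema

ORDERING = ("positive", "no_change", "negative")


def info_matrix_oracle(design, beta):
    """Straight-loop oracle: M = sum_s X_s' (diag(p) - p p') X_s."""
    schema = design.schema
    p_dim = schema.n_columns
    M = np.zeros((p_dim, p_dim))
    for cs in design.choice_sets:
        X = np.stack([effects_code(schema, prof) for prof in cs.profiles])
        u = X @ beta
        e = np.exp(u - u.max())
        p = e / e.sum()
        M += X.T @ (np.diag(p) - np.outer(p, p)) @ X
    return M


class TestBalancePlan:
    def test_study_geometry_constancy_counts(self, study_schema):
        plan = plan_attribute_balance(study_schema, 54, 5, seed=2)
        counts = plan.constancy_counts()
        assert all(len(a) == 6 for a in plan.assignment)
        assert set(counts.values()) <= {29, 30}
        assert sum(counts.values()) == 54 * 6

    def test_exact_divisibility(self):
        schema = make_schema(3)
        plan = plan_attribute_balance(schema, 3, 2, seed=0)
        assert set(plan.constancy_counts().values()) == {1}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pairwise_balance_exact_small_case(self, seed):
        """K=4, 6 sets, 2 constants each: all six unordered pairs exactly once."""
        schema = make_schema(4)
        plan = plan_attribute_balance(schema, 6, 2, seed=seed)
        assert set(plan.pair_counts().values()) == {1}

    def test_pairwise_balance_slack_study_geometry(self, study_schema):
        plan = plan_attribute_balance(study_schema, 54, 5, seed=3)
        vals = list(plan.pair_counts().values())
        assert max(vals) - min(vals) <= 4  # documented slack of the plan builder

    def test_infeasible_max_varying(self, toy2):
        with pytest.raises(DesignError):
            plan_attribute_balance(toy2, 4, 3)


class TestInformationMatrix:
    def test_closed_form_at_zero(self, tiny_design):
        """At beta = 0 every pair is 50/50, so M = 1/4 sum d d'."""
        D = _difference_matrix(tiny_design)
        expected = 0.25 * D.T @ D
        M = mnl_information_matrix(tiny_design, np.zeros(tiny_design.schema.n_columns))
        assert M == pytest.approx(expected, abs=1e-12)

    def test_identical_profiles_contribute_nothing(self, toy2):
        prof = {"a1": "positive", "a2": "negative"}
        cs = ChoiceSet(id="s1", profiles=(dict(prof), dict(prof)),
                       incidental_constant_ids=frozenset(toy2.ids))
        design = pp.ChoiceDesign(schema=toy2, choice_sets=(cs,), blocks={"s1": 0})
        M = mnl_information_matrix(design, np.array([0.5, 0.0, -0.5, 0.0]))
        assert np.array_equal(M, np.zeros((4, 4)))

    def test_matches_straight_loop_oracle(self, tiny_design):
        rng = np.random.default_rng(1)
        for _ in range(3):
            beta = rng.normal(scale=0.7, size=tiny_design.schema.n_columns)
            M = mnl_information_matrix(tiny_design, beta)
            assert M == pytest.approx(info_matrix_oracle(tiny_design, beta), abs=1e-10)

    def test_symmetric_psd(self, tiny_design):
        beta = np.full(tiny_design.schema.n_columns, 0.3)
        M = mnl_information_matrix(tiny_design, beta)
        assert np.allclose(M, M.T)
        assert np.linalg.eigvalsh(M).min() >= -1e-10


class TestBayesianDCriterion:
    def test_single_draw_closed_form(self, tiny_design):
        D = _difference_matrix(tiny_design)
        expected = np.linalg.slogdet(0.25 * D.T @ D)[1]
        got = bayesian_d_criterion(tiny_design, np.zeros((1, tiny_design.schema.n_columns)))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_always_constant_attribute_is_singular(self, toy2):
        """An attribute constant in every set leaves dead columns -> sentinel."""
        sets = []
        for i, (l1, l2) in enumerate([("positive", "negative"), ("negative", "no_change")]):
            sets.append(
                ChoiceSet(
                    id=f"s{i}",
                    profiles=(
                        {"a1": l1, "a2": "no_change"},
                        {"a1": l2, "a2": "no_change"},
                    ),
                    balanced_constant_ids=frozenset({"a2"}),
                )
            )
        design = pp.ChoiceDesign(schema=toy2, choice_sets=tuple(sets),
                                 blocks={cs.id: 0 for cs in sets})
        assert bayesian_d_criterion(design, np.zeros((4, 4))) == float("-inf")

    def test_monte_carlo_self_consistency(self, toy2):
        """256 draws agree with 10,000 draws within Monte-Carlo error."""
        prior = pp.build_ordered_prior(toy2, sd=0.5, draws=256, seed=5)
        design = pp.optimize_design(toy2, prior, n_sets=6, n_varying_max=2,
                                    restarts=2, seed=6)
        big = PriorSpec(mean=prior.mean, covariance=prior.covariance,
                        draws=10_000, seed=7)
        c_small = bayesian_d_criterion(design, sample_prior(prior))
        c_big = bayesian_d_criterion(design, sample_prior(big))
        assert c_small == pytest.approx(c_big, abs=0.2)


class TestDominance:
    def _cs(self, toy2, l1a, l2a, l1b, l2b):
        return ChoiceSet(
            id="s",
            profiles=({"a1": l1a, "a2": l2a}, {"a1": l1b, "a2": l2b}),
        )

    def test_all_positive_dominates_all_negative(self, toy2):
        cs = self._cs(toy2, "positive", "positive", "negative", "negative")
        assert dominance_check(cs, ORDERING)

    def test_identical_profiles_not_dominated(self, toy2):
        cs = self._cs(toy2, "positive", "negative", "positive", "negative")
        assert not dominance_check(cs, ORDERING)

    def test_trade_off_not_dominated(self, toy2):
        cs = self._cs(toy2, "positive", "negative", "negative", "positive")
        assert not dominance_check(cs, ORDERING)

    def test_swap_invariance(self, toy2):
        cs = self._cs(toy2, "positive", "no_change", "negative", "no_change")
        assert dominance_check(cs, ORDERING) == dominance_check(cs.swapped(), ORDERING)


class TestOptimizeDesign:
    def test_restart_monotonicity(self, toy4):
        prior = pp.build_ordered_prior(toy4, draws=32, seed=1)
        c1 = pp.optimize_design(toy4, prior, 8, 3, restarts=1, seed=2).criterion_value
        c8 = pp.optimize_design(toy4, prior, 8, 3, restarts=8, seed=2).criterion_value
        assert c8 >= c1

    def test_criterion_value_matches_reevaluation(self, tiny_design, toy4):
        prior = pp.build_ordered_prior(toy4, draws=64, seed=11)
        assert tiny_design.criterion_value == pytest.approx(
            bayesian_d_criterion(tiny_design, sample_prior(prior)), rel=1e-12
        )

    def test_criterion_invariant_to_profile_swap_and_set_order(self, tiny_design, toy4):
        prior = pp.build_ordered_prior(toy4, draws=64, seed=11)
        draws = sample_prior(prior)
        base = bayesian_d_criterion(tiny_design, draws)
        swapped = pp.ChoiceDesign(
            schema=tiny_design.schema,
            choice_sets=tuple(cs.swapped() for cs in tiny_design.choice_sets),
            blocks=tiny_design.blocks,
        )
        permuted = pp.ChoiceDesign(
            schema=tiny_design.schema,
            choice_sets=tiny_design.choice_sets[::-1],
            blocks=tiny_design.blocks,
        )
        assert bayesian_d_criterion(swapped, draws) == pytest.approx(base, rel=1e-12)
        assert bayesian_d_criterion(permuted, draws) == pytest.approx(base, rel=1e-12)

    def test_no_dominated_sets_under_prior_ordering(self, tiny_design):
        for cs in tiny_design.choice_sets:
            assert not dominance_check(cs, ORDERING)

    def test_planned_constants_at_no_change(self, tiny_design):
        for cs in tiny_design.choice_sets:
            for aid in cs.balanced_constant_ids:
                assert cs.profiles[0][aid] == "no_change"
                assert cs.profiles[1][aid] == "no_change"

    def test_beats_random_designs_sharing_plan(self, toy4):
        prior = pp.build_ordered_prior(toy4, draws=64, seed=11)
        plan = plan_attribute_balance(toy4, 12, 3, seed=4)
        design = pp.optimize_design(toy4, prior, 12, 3, restarts=2, seed=4, plan=plan)
        draws = sample_prior(prior)
        best_random = max(
            bayesian_d_criterion(
                random_feasible_design(toy4, plan, prior.mean, seed=k), draws
            )
            for k in range(25)
        )
        assert design.criterion_value >= best_random

    def test_blocks_partition_equally(self, toy4):
        prior = pp.build_ordered_prior(toy4, draws=32, seed=1)
        design = pp.optimize_design(toy4, prior, 9, 3, n_blocks=3, restarts=1, seed=2)
        sizes = [len(design.sets_in_block(b)) for b in range(3)]
        assert sizes == [3, 3, 3]

    def test_indivisible_blocks_rejected(self, toy4):
        prior = pp.build_ordered_prior(toy4, draws=16, seed=1)
        with pytest.raises(DesignError):
            pp.optimize_design(toy4, prior, 8, 3, n_blocks=3)


class TestDesignCsvRoundTrip:
    def test_lossless(self, tiny_design, tmp_path):
        path = tmp_path / "design.csv"
        tiny_design.to_csv(path)
        loaded = pp.ChoiceDesign.from_csv(path, tiny_design.schema)
        assert loaded.blocks == tiny_design.blocks
        for a, b in zip(loaded.choice_sets, tiny_design.choice_sets):
            assert a.id == b.id
            assert a.profiles == b.profiles
            assert a.balanced_constant_ids == b.balanced_constant_ids
            assert a.incidental_constant_ids == b.incidental_constant_ids
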