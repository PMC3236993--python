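import math

import numpy as np
import pytest

from aclcea.evidence import CLASSES, ActivityClass, ActivityDistribution
from aclcea.tree import (
    ModelParams,
    TreeNode,
    build_strategy_tree,
    calibrate_residuals,
    enumerate_paths,
    render_tree,
    replace_params,
    rollback,
    run_strategies,
    tree_from_dict,
    tree_to_dict,
    validate,
)
from aclcea.utilities import UtilityKey

from conftest import random_tree


def point_mass(c):
    return ActivityDistribution({k: (1.0 if k is c else 0.0) for k in CLASSES})


@pytest.fixture(scope="module")
def flat_key():
    return UtilityKey(means={c: 0.1 * int(c) + 0.3 for c in CLASSES})


class TestModelParams:
    def test_probability_bounds(self, baseline_params):
        with pytest.raises(ValueError, match="p_fail"):
            replace_params(baseline_params, p_fail=1.5)

    def test_negative_cost_rejected(self, baseline_params):
        with pytest.raises(ValueError, match="cost_surgical"):
            replace_params(baseline_params, cost_surgical=-1)

    def test_unknown_field_rejected(self, baseline_params):
        with pytest.raises(ValueError, match="unknown"):
            replace_params(baseline_params, p_typo=0.5)

    def test_baseline_values(self, baseline_params):
        assert baseline_params.p_fail == 0.035
        assert baseline_params.p_crossover == 0.16
        assert baseline_params.p_seq_operative == 0.34
        assert baseline_params.p_seq_conservative == 0.77
        assert baseline_params.split_oa_operative == 0.86
        assert baseline_params.split_oa_conservative == 0.74
        assert baseline_params.sequelae_class is ActivityClass.II
        assert baseline_params.horizon_months == 90


class TestBuildStrategyTree:
    def test_reconstruction_contains_published_splits(self, baseline_params, baseline_key):
        tree = build_strategy_tree(baseline_params, baseline_key, "reconstruction")
        probs = {round(p, 10) for p, _ in tree.children}
        assert probs == {0.34, 0.66}
        sequelae = next(child for p, child in tree.children if p == 0.34)
        assert {round(p, 10) for p, _ in sequelae.children} == {0.86, 0.14}

    def test_conservative_crossover_branch_adds_surgical_cost(
        self, baseline_params, baseline_key
    ):
        tree = build_strategy_tree(baseline_params, baseline_key, "conservative")
        base = (
            baseline_params.cost_conservative
            + baseline_params.residual_cost_conservative
        )
        crossover_leaves = [
            (p, cost)
            for p, cost, _, label in enumerate_paths(tree)
            if "/crossover" in label
        ]
        assert crossover_leaves
        assert sum(p for p, _ in crossover_leaves) == pytest.approx(0.16, abs=1e-12)
        no_seq_cross = [
            cost
            for p, cost, _, label in enumerate_paths(tree)
            if label.startswith("no_sequelae/crossover")
        ]
        assert all(
            c == pytest.approx(base + baseline_params.cost_surgical) for c in no_seq_cross
        )

    def test_collapsed_tree(self, baseline_params, flat_key):
        params = replace_params(
            baseline_params,
            p_seq_operative=0.0,
            p_fail=0.0,
            dist_operative=point_mass(ActivityClass.V),
            residual_cost_operative=0.0,
        )
        cost, effect = rollback(build_strategy_tree(params, flat_key, "reconstruction"))
        assert cost == pytest.approx(params.cost_surgical)
        assert effect == pytest.approx(flat_key.mean(ActivityClass.V))

    def test_unknown_strategy(self, baseline_params, flat_key):
        with pytest.raises(ValueError, match="strategy"):
            build_strategy_tree(baseline_params, flat_key, "homeopathy")

    def test_built_trees_validate(self, baseline_params, baseline_key):
        for strategy in ("reconstruction", "conservative"):
            report = validate(build_strategy_tree(baseline_params, baseline_key, strategy))
            assert report.ok, report.violations


class TestValidate:
    def test_probability_sum_violation_named(self):
        bad = TreeNode(
            kind="chance",
            label="broken",
            children=[
                (0.5, TreeNode(kind="terminal", payoff_cost=1, payoff_effect=0.5)),
                (0.4, TreeNode(kind="terminal", payoff_cost=2, payoff_effect=0.6)),
            ],
        )
        report = validate(bad)
        assert not report.ok
        assert any("broken" in v for v in report.violations)

    def test_non_finite_payoff_flagged(self):
        bad = TreeNode(kind="terminal", label="inf", payoff_cost=math.inf, payoff_effect=0.5)
        report = validate(bad)
        assert not report.ok

    def test_random_valid_trees_pass(self):
        for seed in range(25):
            tree = random_tree(np.random.default_rng(seed))
            assert validate(tree).ok


class TestRollback:
    def test_single_terminal_identity(self):
        leaf = TreeNode(kind="terminal", payoff_cost=123.4, payoff_effect=0.77)
        assert rollback(leaf) == (123.4, 0.77)

    def test_invalid_tree_raises(self):
        bad = TreeNode(
            kind="chance",
            children=[(0.5, TreeNode(kind="terminal", payoff_cost=0, payoff_effect=0))],
        )
        with pytest.raises(ValueError, match="invalid tree"):
            rollback(bad)

    def test_rollback_equals_path_enumeration_oracle(self):
        # 100 seeded random instances vs the independent exhaustive oracle
        for seed in range(100):
            tree = random_tree(np.random.default_rng(seed))
            cost, effect = rollback(tree)
            oracle_cost = sum(p * c for p, c, _, _ in enumerate_paths(tree))
            oracle_effect = sum(p * e for p, _, e, _ in enumerate_paths(tree))
            assert cost == pytest.approx(oracle_cost, rel=1e-9, abs=1e-9)
            assert effect == pytest.approx(oracle_effect, rel=1e-9, abs=1e-9)

    def test_literal_reconstruction_cost(self, baseline_params, baseline_key):
        # hand rollback: 9926*1.035 + 0.34*(0.86*17361 + 0.14*6382)
        params = replace_params(baseline_params, residual_cost_operative=0.0)
        cost, _ = rollback(build_strategy_tree(params, baseline_key, "reconstruction"))
        assert cost == pytest.approx(15653.55, abs=0.01)

    def test_literal_conservative_cost(self, baseline_params, baseline_key):
        # hand rollback: 2535 + 0.16*9926 + 0.77*(0.74*17361 + 0.26*6382)
        params = replace_params(baseline_params, residual_cost_conservative=0.0)
        cost, _ = rollback(build_strategy_tree(params, baseline_key, "conservative"))
        assert cost == pytest.approx(15293.13, abs=0.01)

    def test_cost_monotone_in_cost_parameters(self, baseline_params, baseline_key):
        base_costs = {
            r.strategy: r.expected_cost
            for r in run_strategies(baseline_params, baseline_key)
        }
        for field in ("cost_surgical", "cost_conservative", "cost_oa", "cost_meniscus"):
            bumped = replace_params(
                baseline_params, **{field: getattr(baseline_params, field) + 500}
            )
            for r in run_strategies(bumped, baseline_key):
                assert r.expected_cost >= base_costs[r.strategy] - 1e-9

    def test_effect_decreases_with_sequelae_probability(self, baseline_params, baseline_key):
        # key.mean[II] is below both arms' no-sequelae expected utility
        effects = {}
        for p_seq in (0.0, 0.34, 0.9):
            params = replace_params(
                baseline_params, p_seq_operative=p_seq, p_seq_conservative=p_seq
            )
            for r in run_strategies(params, baseline_key):
                effects.setdefault(r.strategy, []).append(r.expected_effect)
        for series in effects.values():
            assert series == sorted(series, reverse=True)

    def test_no_adverse_branches_reduces_to_base(self, baseline_params, baseline_key):
        from aclcea.utilities import expected_utility

        params = replace_params(
            baseline_params,
            p_fail=0.0,
            p_crossover=0.0,
            p_seq_operative=0.0,
            p_seq_conservative=0.0,
            residual_cost_operative=0.0,
            residual_cost_conservative=0.0,
        )
        by_name = {r.strategy: r for r in run_strategies(params, baseline_key)}
        assert by_name["reconstruction"].expected_cost == pytest.approx(9926)
        assert by_name["conservative"].expected_cost == pytest.approx(2535)
        assert by_name["reconstruction"].expected_effect == pytest.approx(
            expected_utility(params.dist_operative, baseline_key)
        )
        assert by_name["conservative"].expected_effect == pytest.approx(
            expected_utility(params.dist_conservative, baseline_key)
        )


class TestCalibrateResiduals:
    def test_reproduces_target_costs(self, baseline_params, baseline_key):
        calibrated = calibrate_residuals(baseline_params, 16038.0, 15466.0)
        by_name = {
            r.strategy: r.expected_cost for r in run_strategies(calibrated, baseline_key)
        }
        assert by_name["reconstruction"] == pytest.approx(16038.0, abs=1e-9)
        assert by_name["conservative"] == pytest.approx(15466.0, abs=1e-9)

    def test_shipped_residuals_match_recalibration(self, baseline_params):
        calibrated = calibrate_residuals(baseline_params, 16038.0, 15466.0)
        assert calibrated.residual_cost_operative == pytest.approx(
            baseline_params.residual_cost_operative, abs=1e-3
        )
        assert calibrated.residual_cost_conservative == pytest.approx(
            baseline_params.residual_cost_conservative, abs=1e-3
        )


class TestSerialization:
    def test_json_roundtrip(self, baseline_params, baseline_key):
        tree = build_strategy_tree(baseline_params, baseline_key, "reconstruction")
        again = tree_from_dict(tree_to_dict(tree))
        assert rollback(again) == pytest.approx(rollback(tree))

    def test_render_contains_labels(self, baseline_params, baseline_key):
        text = render_tree(build_strategy_tree(baseline_params, baseline_key, "conservative"))
        assert "sequelae" in text and "crossover" in text
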