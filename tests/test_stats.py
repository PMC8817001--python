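"""Coordination statistics against enumeration oracles and hand calculations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tacitcoord import (
    GameBoard,
    ResponseMatrix,
    Rule,
    RuleResult,
    compare_strategy_rates,
    coordination_function,
    coordination_index,
    game_tag,
    ica,
    ica_scores,
    random_picking_ci,
    strategy_rate,
    utilization_ratio,
    utilization_vs_ci_regression,
)
from tacitcoord.stats import SR_COLUMNS, permutation_f_test, strategic_profiles


def ci_pair_oracle(choices):
    """Count coinciding unordered pairs / C(N, 2)."""
    pairs = list(itertools.combinations(choices, 2))
    return sum(a == b for a, b in pairs) / len(pairs)


class TestCoordinationIndex:
    def test_all_same_is_one(self):
        assert coordination_index(["LLR"] * 10).value == 1.0

    def test_all_distinct_is_zero(self):
        assert coordination_index(["LL", "LR", "RL", "RR"]).value == 0.0

    def test_three_one_split(self):
        # 3 coinciding pairs out of 6
        assert coordination_index(["LR", "LR", "LR", "RL"]).value == 0.5

    def test_requires_two_choices(self):
        with pytest.raises(ValueError):
            coordination_index(["LR"])

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        options = ["LL", "LR", "RL", "RR"]
        for _ in range(200):
            n = int(rng.integers(2, 9))
            choices = [options[i] for i in rng.integers(0, 4, size=n)]
            assert coordination_index(choices).value == pytest.approx(
                ci_pair_oracle(choices)
            )

    def test_random_picking_ci_closed_form(self):
        for n in range(1, 6):
            board = GameBoard(
                "b", 20, 4, tuple((3 + i, 1) for i in range(n)), (0, 1), (19, 1)
            )
            assert random_picking_ci(board) == pytest.approx(1 / 2**n)


class TestCoordinationFunction:
    @pytest.mark.parametrize(
        "a, b, expected", [("LLRR", "LLRR", 1), ("LLRR", "LLRL", 0)]
    )
    def test_full_match_only(self, a, b, expected):
        assert coordination_function(a, b) == expected

    def test_reflexive(self):
        for a in ("L", "RRL", "LRLR"):
            assert coordination_function(a, a) == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            coordination_function("LL", "LLL")


def _matrix(rows, boards, n_predefined=None):
    players = [f"p{i}" for i in range(len(rows))]
    choices = {
        (p, b.board_id): row[j]
        for p, row in zip(players, rows)
        for j, b in enumerate(boards)
    }
    return ResponseMatrix(
        players=players,
        boards=list(boards),
        choices=choices,
        n_predefined=n_predefined or len(boards),
    )


class TestICA:
    def test_unanimous_population(self, two_circle_board, one_circle_board):
        m = _matrix([["LR", "L"]] * 4, [two_circle_board, one_circle_board])
        assert ica_scores(m).tolist() == [1.0] * 4

    def test_isolated_player_scores_zero(self, two_circle_board):
        m = _matrix([["LR"], ["LR"], ["RL"]], [two_circle_board])
        assert ica(m, "p2") == 0.0

    def test_single_match_worked_example(self, two_circle_board, one_circle_board):
        # 3 players, 2 games; p0 matches p1 in game 1 only: 1 of (N-1)*t = 4
        m = _matrix(
            [["LR", "L"], ["LR", "R"], ["RL", "R"]],
            [two_circle_board, one_circle_board],
        )
        assert ica(m, "p0") == pytest.approx(0.25)

    def test_predefined_subset_only(self, two_circle_board, one_circle_board):
        # second board is a random filler; agreement there must not count
        m = _matrix(
            [["LR", "L"], ["RL", "L"]],
            [two_circle_board, one_circle_board],
            n_predefined=1,
        )
        assert ica_scores(m, predefined_only=True).tolist() == [0.0, 0.0]
        assert ica_scores(m, predefined_only=False).tolist() == [0.5, 0.5]

    def test_invariant_to_player_and_game_relabeling(
        self, two_circle_board, one_circle_board
    ):
        rng = np.random.default_rng(8)
        rows = [
            [["LR", "RL"][rng.integers(2)], ["L", "R"][rng.integers(2)]]
            for _ in range(6)
        ]
        m = _matrix(rows, [two_circle_board, one_circle_board])
        base = ica_scores(m)
        perm = rng.permutation(6)
        m2 = _matrix([rows[i] for i in perm], [two_circle_board, one_circle_board])
        for new_idx, old_idx in enumerate(perm):
            assert ica_scores(m2)[f"p{new_idx}"] == pytest.approx(base[f"p{old_idx}"])
        # swapping game order leaves every score unchanged
        m3 = _matrix(
            [[r[1], r[0]] for r in rows], [one_circle_board, two_circle_board]
        )
        assert np.allclose(ica_scores(m3).to_numpy(), base.to_numpy())

    def test_duplicating_a_player_cannot_decrease_their_score(
        self, two_circle_board, one_circle_board
    ):
        rng = np.random.default_rng(9)
        for _ in range(20):
            rows = [
                [["LR", "RL"][rng.integers(2)], ["L", "R"][rng.integers(2)]]
                for _ in range(4)
            ]
            m = _matrix(rows, [two_circle_board, one_circle_board])
            before = ica(m, "p0")
            m2 = _matrix(rows + [rows[0]], [two_circle_board, one_circle_board])
            assert ica(m2, "p0") >= before - 1e-12

    def test_single_player_rejected(self, two_circle_board):
        with pytest.raises(ValueError):
            ica_scores(_matrix([["LR"]], [two_circle_board]))


class TestGameTags:
    def test_inapplicable_rule_tags_zero(self):
        res = RuleResult(Rule.EQUALITY, False)
        assert game_tag("LR", res) == 0

    def test_followed_and_deviated(self):
        res = RuleResult(Rule.CLOSENESS, True, "LLRR")
        assert game_tag("LLRR", res) == 1
        assert game_tag("LRRR", res) == -1

    def test_coinciding_rules_both_tag_one(self):
        choice = "LLRR"
        for rule in (Rule.CLOSENESS, Rule.EQUALITY):
            assert game_tag(choice, RuleResult(rule, True, "LLRR")) == 1


class TestStrategyRate:
    def test_worked_examples(self):
        # 8 available, 5 followed; and 10 available, 4 followed
        assert strategy_rate([1] * 5 + [-1] * 3 + [0] * 6) == pytest.approx(5 / 8)
        assert strategy_rate([1] * 4 + [-1] * 6 + [0] * 4) == pytest.approx(0.40)

    def test_always_followed(self):
        assert strategy_rate([1, 1, 0, 1]) == 1.0

    def test_never_available_is_undefined(self):
        assert math.isnan(strategy_rate([0, 0, 0]))

    def test_unavailable_games_do_not_affect_rate(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            tags = list(rng.choice([-1, 1], size=6))
            padded = tags + [0] * int(rng.integers(0, 5))
            rng.shuffle(padded)
            assert strategy_rate(padded) == pytest.approx(strategy_rate(tags))


class TestUtilization:
    def test_everyone_follows(self, two_circle_board):
        m = _matrix([["LR"]] * 5, [two_circle_board])
        assert utilization_ratio(m, two_circle_board, Rule.CLOSENESS) == 1.0

    def test_inapplicable_marker(self, one_circle_board):
        m = _matrix([["L"], ["R"]], [one_circle_board])
        assert utilization_ratio(m, one_circle_board, Rule.CLOSENESS) is None

    def test_direct_count(self, two_circle_board):
        rows = [["LR"]] * 31 + [["RL"]] * 62
        m = _matrix(rows, [two_circle_board])
        assert utilization_ratio(m, two_circle_board, Rule.CLOSENESS) == pytest.approx(
            31 / 93, abs=1e-4
        )


class TestUtilizationRegression:
    def test_exact_linear_relationship(self):
        ci = np.linspace(0.1, 0.9, 8)
        util = 0.3 + 0.5 * ci
        res = utilization_vs_ci_regression(ci, util)
        assert res.slope == pytest.approx(0.5, abs=1e-10)
        assert res.p_value < 1e-10

    def test_type_one_error_rate(self):
        """Independent utilization: slope test should rarely reject."""
        rng = np.random.default_rng(21)
        ci = np.linspace(0.1, 0.9, 10)
        non_significant = sum(
            utilization_vs_ci_regression(ci, rng.uniform(0, 1, size=10)).p_value
            > 0.05
            for _ in range(60)
        )
        assert non_significant >= 54  # >= 90%

    def test_constant_ci_rejected(self):
        with pytest.raises(ValueError):
            utilization_vs_ci_regression([0.5] * 5, [0.1, 0.2, 0.3, 0.4, 0.5])

    def test_positive_slope_on_synthetic_cohorts(self):
        """Rule-followers coordinate more on easy boards, so pooled per-game
        utilization must rise with the game's coordination index."""
        from tacitcoord import default_population, simulate_population
        from tacitcoord.pipeline import score_cohort

        for seed in range(3):
            matrix = simulate_population(default_population(n_agents=93, seed=seed))
            _, per_game = score_cohort(matrix)
            ci, util = [], []
            for rule in ("closeness", "equality", "accession"):
                col = per_game[f"utilization_{rule}"]
                mask = col.notna()
                ci += per_game.loc[mask, "ci"].tolist()
                util += col[mask].tolist()
            res = utilization_vs_ci_regression(ci, util)
            assert res.slope > 0
            assert res.p_value < 0.05


class TestCompareStrategyRates:
    def _profiles(self, arr):
        return pd.DataFrame(arr, columns=SR_COLUMNS)

    def test_identical_columns_not_significant(self):
        rng = np.random.default_rng(31)
        base = rng.uniform(0.2, 0.8, size=20)
        comp = compare_strategy_rates(self._profiles(np.column_stack([base] * 3)))
        assert comp.f_stat == pytest.approx(0.0, abs=1e-12)
        assert (comp.pairwise["p_value"] > 0.9).all()

    def test_shifted_column_flagged_in_both_pairwise_tests(self):
        rng = np.random.default_rng(32)
        a = rng.normal(0.5, 0.05, size=30)
        b = rng.normal(0.5, 0.05, size=30)
        c = rng.normal(0.9, 0.05, size=30)  # accession column shifted
        comp = compare_strategy_rates(self._profiles(np.column_stack([a, b, c])))
        assert comp.p_value < 0.001
        flagged = comp.pairwise[comp.pairwise.rule_b == "sr_accession"]
        assert (flagged["p_value"] < 0.001).all()
        unflagged = comp.pairwise[
            (comp.pairwise.rule_a == "sr_closeness")
            & (comp.pairwise.rule_b == "sr_equality")
        ]
        assert (unflagged["p_value"] > 0.05).all()

    def test_permutation_p_agrees_with_f_test(self):
        rng = np.random.default_rng(33)
        arr = rng.normal(0.5, 0.1, size=(40, 3))
        profiles = self._profiles(arr)
        p_f = compare_strategy_rates(profiles).p_value
        p_perm = permutation_f_test(profiles, n_perm=3000, seed=0)
        assert abs(p_f - p_perm) < 0.08

    def test_undefined_profiles_excluded_with_warning(self):
        arr = np.random.default_rng(34).uniform(0, 1, size=(10, 3))
        profiles = self._profiles(arr)
        profiles.iloc[0, 2] = np.nan
        with pytest.warns(UserWarning, match="excluding 1"):
            comp = compare_strategy_rates(profiles)
        assert comp.n_players == 9


class TestStrategicProfiles:
    def test_hand_built_cohort(self, tiny_matrix):
        profiles = strategic_profiles(tiny_matrix)
        # board b2: all three rules imply LR; board b1: nothing applies
        assert profiles.loc["p1"].tolist() == [1.0, 1.0, 1.0]
        assert profiles.loc["p3"].tolist() == [0.0, 0.0, 0.0]
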