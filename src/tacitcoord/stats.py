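"""Coordination statistics: CI, CF, iCA, game tags, strategy rates.

The coordination index (CI) of a game is the probability that two players
drawn at random without replacement gave the same full assignment,

    c = sum_j m_j (m_j - 1) / (N (N - 1)),

where ``m_j`` counts the players who chose solution ``j``.  A player's
individual coordination ability (iCA) is their mean pairwise agreement with
every other player over the predefined games.  Per player, game, and rule, a
game tag (GT) is +1 when the rule applied and the player followed it, -1
when it applied and they did not, and 0 when it did not apply; the strategy
rate (SR) for a rule is the fraction of rule-available games the player
followed it in.  The (SR_closeness, SR_equality, SR_accession) triple is the
player's strategic profile.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .boards import Assignment, GameBoard, ResponseMatrix, enumerate_assignments
from .rules import RULES, BoardRuleProfile, Rule, RuleResult, profile_board

SR_COLUMNS = ["sr_closeness", "sr_equality", "sr_accession"]
_RULE_TO_SR = {
    Rule.CLOSENESS: "sr_closeness",
    Rule.EQUALITY: "sr_equality",
    Rule.ACCESSION: "sr_accession",
}


@dataclass(frozen=True)
class CoordinationIndex:
    board_id: str
    value: float
    n_players: int
    solution_counts: Mapping[Assignment, int]


def coordination_function(a: Assignment, b: Assignment) -> int:
    """1 iff two full assignments are identical (any differing circle breaks it)."""
    if len(a) != len(b):
        raise ValueError(f"assignment length mismatch: {a!r} vs {b!r}")
    return int(a == b)


def coordination_index(
    choices: Sequence[Assignment], board_id: str = ""
) -> CoordinationIndex:
    """Probability that two distinct random players coincide on this game."""
    n = len(choices)
    if n < 2:
        raise ValueError("coordination index requires at least 2 choices")
    lengths = {len(c) for c in choices}
    if len(lengths) != 1:
        raise ValueError("choices have differing lengths")
    counts = Counter(choices)
    value = sum(m * (m - 1) for m in counts.values()) / (n * (n - 1))
    return CoordinationIndex(board_id, value, n, dict(counts))


def random_picking_ci(board: GameBoard) -> float:
    """Expected CI when players choose uniformly from the solution space.

    Computed by enumerating the full assignment space and averaging pairwise
    agreement of two independent uniform choosers; equals 1 / 2**n_circles.
    """
    assignments = list(enumerate_assignments(board.n_circles))
    n = len(assignments)
    agree = Fraction(0)
    for a in assignments:
        # pairwise agreement is diagonal-only: sum_a P(a)^2
        agree += Fraction(1, n) * Fraction(1, n) * coordination_function(a, a)
    return float(agree)


def ica_scores(matrix: ResponseMatrix, predefined_only: bool = True) -> pd.Series:
    """Individual coordination ability for every player.

    iCA(i) = sum over other players j and games k of CF(i,j,k) / ((N-1) t),
    by default over the predefined games only (the randomized fillers are not
    shared between players in the emulated design).
    """
    if matrix.n_players < 2:
        raise ValueError("iCA requires at least 2 players")
    boards = matrix.predefined_boards if predefined_only else matrix.boards
    t = len(boards)
    n = matrix.n_players
    totals = np.zeros(n)
    for board in boards:
        col = matrix.column(board)
        counts = Counter(col)
        # number of *other* players agreeing with player i on this game
        totals += np.array([counts[c] - 1 for c in col], dtype=float)
    values = totals / ((n - 1) * t)
    return pd.Series(values, index=pd.Index(matrix.players, name="player"), name="ica")


def ica(matrix: ResponseMatrix, player: str, predefined_only: bool = True) -> float:
    """iCA of a single player (see :func:`ica_scores`)."""
    return float(ica_scores(matrix, predefined_only=predefined_only)[player])


def game_tag(choice: Assignment, rule_result: RuleResult) -> int:
    """+1 followed, -1 available-but-not-followed, 0 rule unavailable."""
    if not rule_result.applicable:
        return 0
    return 1 if choice == rule_result.assignment else -1


def gt_table(
    matrix: ResponseMatrix,
    board_profiles: Optional[Mapping[str, BoardRuleProfile]] = None,
) -> pd.DataFrame:
    """Game tags for every (player, board, rule), long-format DataFrame."""
    if board_profiles is None:
        board_profiles = {b.board_id: profile_board(b) for b in matrix.boards}
    records = []
    for board in matrix.boards:
        prof = board_profiles[board.board_id]
        for player in matrix.players:
            choice = matrix.choices[(player, board.board_id)]
            for rule in RULES:
                records.append(
                    (player, board.board_id, rule.value, game_tag(choice, prof[rule]))
                )
    return pd.DataFrame.from_records(
        records, columns=["player", "board_id", "rule", "gt"]
    )


def strategy_rate(gt_row: Iterable[int]) -> float:
    """SR = (# games with GT=+1) / (# games with GT != 0); NaN when never available."""
    tags = list(gt_row)
    available = sum(1 for t in tags if t != 0)
    if available == 0:
        return math.nan
    followed = sum(1 for t in tags if t == 1)
    return followed / available


def strategic_profiles(
    matrix: ResponseMatrix,
    board_profiles: Optional[Mapping[str, BoardRuleProfile]] = None,
) -> pd.DataFrame:
    """Per-player strategic profile: one SR per rule, over all boards.

    Columns ``sr_closeness, sr_equality, sr_accession``; NaN marks a rule
    that was never applicable for that player's set of boards.
    """
    gt = gt_table(matrix, board_profiles)
    out = pd.DataFrame(
        index=pd.Index(matrix.players, name="player"), columns=SR_COLUMNS, dtype=float
    )
    grouped = gt.groupby(["player", "rule"])["gt"]
    followed = grouped.apply(lambda s: (s == 1).sum())
    available = grouped.apply(lambda s: (s != 0).sum())
    for rule in RULES:
        col = _RULE_TO_SR[rule]
        for player in matrix.players:
            avail = available.get((player, rule.value), 0)
            out.loc[player, col] = (
                followed[(player, rule.value)] / avail if avail else math.nan
            )
    return out


def utilization_ratio(
    matrix: ResponseMatrix, board: GameBoard, rule: Rule
) -> Optional[float]:
    """Share of players whose choice equals the rule's implied assignment.

    Returns None when the rule is not applicable on the board (the
    "Not applicable" cells of the per-game summary).
    """
    result = profile_board(board)[Rule(rule)]
    if not result.applicable:
        return None
    col = matrix.column(board)
    return sum(1 for c in col if c == result.assignment) / len(col)


def per_game_summary(matrix: ResponseMatrix) -> pd.DataFrame:
    """Per-board CI, random-picking CI, and per-rule utilization ratios."""
    rows = []
    for board in matrix.boards:
        ci = coordination_index(matrix.column(board), board.board_id)
        row = {
            "board_id": board.board_id,
            "n_circles": board.n_circles,
            "ci": ci.value,
            "random_ci": random_picking_ci(board),
        }
        for rule in RULES:
            row[f"utilization_{rule.value}"] = utilization_ratio(matrix, board, rule)
        rows.append(row)
    return pd.DataFrame(rows).set_index("board_id")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    r_value: float


def utilization_vs_ci_regression(
    ci_values: Sequence[float], utilization: Sequence[float]
) -> RegressionResult:
    """OLS of rule utilization on game CI with a two-sided slope test.

    A positive slope says the rule is followed more on easier games.
    """
    x = np.asarray(ci_values, dtype=float)
    y = np.asarray(utilization, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 (CI, utilization) pairs")
    if np.ptp(x) == 0:
        raise ValueError("CI values are constant; slope is undefined")
    res = sps.linregress(x, y)
    return RegressionResult(res.slope, res.intercept, res.pvalue, res.rvalue)


@dataclass(frozen=True)
class StrategyRateComparison:
    f_stat: float
    p_value: float
    pairwise: pd.DataFrame  # columns: rule_a, rule_b, mean_diff, p_value
    n_players: int


def compare_strategy_rates(profiles: pd.DataFrame) -> StrategyRateComparison:
    """One-way ANOVA across the three SR dimensions plus Tukey HSD pairwise tests.

    Players with any undefined SR are dropped with a warning.
    """
    complete = profiles[SR_COLUMNS].dropna()
    dropped = len(profiles) - len(complete)
    if dropped:
        warnings.warn(
            f"excluding {dropped} player(s) with undefined strategy rates",
            stacklevel=2,
        )
    if len(complete) < 2:
        raise ValueError("need at least 2 players with all three SRs defined")
    groups = [complete[c].to_numpy() for c in SR_COLUMNS]
    f_stat, p_value = sps.f_oneway(*groups)
    tukey = sps.tukey_hsd(*groups)
    rows = []
    for i in range(3):
        for j in range(i + 1, 3):
            rows.append(
                {
                    "rule_a": SR_COLUMNS[i],
                    "rule_b": SR_COLUMNS[j],
                    "mean_diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                    "p_value": float(tukey.pvalue[i, j]),
                }
            )
    return StrategyRateComparison(
        float(f_stat), float(p_value), pd.DataFrame(rows), len(complete)
    )


def permutation_f_test(
    profiles: pd.DataFrame, n_perm: int = 2000, seed: int | None = 0
) -> float:
    """Permutation p-value for the SR one-way F test (small-sample fallback).

    Within each player, the three SR labels are shuffled, which preserves the
    per-player value sets under the null of exchangeable dimensions.
    """
    complete = profiles[SR_COLUMNS].dropna().to_numpy()
    if complete.shape[0] < 2:
        raise ValueError("need at least 2 complete profiles")
    observed, _ = sps.f_oneway(*complete.T)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permuted(complete, axis=1)
        f, _ = sps.f_oneway(*perm.T)
        if f >= observed:
            count += 1
    return (count + 1) / (n_perm + 1)
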