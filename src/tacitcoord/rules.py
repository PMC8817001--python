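"""Focal-point selection rules for "Assign Circles" boards.

Three heuristics are modeled, each of which may or may not apply on a given
board; a rule applies only when it pins down a *unique* full assignment:

* **closeness** — attach each circle to its nearer square; inapplicable if
  any circle is equidistant from the two squares.
* **accession** — partition circles into coherent groups (4-connected on the
  grid: horizontal/vertical neighbors) and attach each whole group to the
  square nearer to the group, group distance being the minimum over its
  circles; inapplicable if any group is equidistant.
* **equality** — if a vertical line splits the circles into two equal
  halves (strictly; a circle on every candidate line blocks the rule, as
  does an odd circle count), attach the left half to the left square and
  the right half to the right square.

Distances are Euclidean between grid points; comparisons use exact integer
squared distances so ties are detected deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .boards import Assignment, GameBoard, Point


class Rule(str, Enum):
    CLOSENESS = "closeness"
    EQUALITY = "equality"
    ACCESSION = "accession"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


RULES = (Rule.CLOSENESS, Rule.EQUALITY, Rule.ACCESSION)


@dataclass(frozen=True)
class RuleResult:
    """Outcome of evaluating one selection rule on one board."""

    rule: Rule
    applicable: bool
    assignment: Optional[Assignment] = None

    def __post_init__(self) -> None:
        if self.applicable != (self.assignment is not None):
            raise ValueError("assignment must be present iff applicable")


@dataclass(frozen=True)
class BoardRuleProfile:
    """All three rule outcomes on one board, plus the predicted-response set."""

    board_id: str
    results: dict[Rule, RuleResult]

    @property
    def predicted_responses(self) -> frozenset[Assignment]:
        """Distinct assignments implied by the applicable rules (may be empty)."""
        return frozenset(
            r.assignment for r in self.results.values() if r.applicable
        )

    def __getitem__(self, rule: Rule) -> RuleResult:
        return self.results[rule]


def _sqdist(a: Point, b: Point) -> int:
    return (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2


def closeness_rule(board: GameBoard) -> RuleResult:
    """Assign each circle to the strictly nearer square, if always possible."""
    labels = []
    for c in board.circles:
        dl = _sqdist(c, board.square_left)
        dr = _sqdist(c, board.square_right)
        if dl == dr:
            return RuleResult(Rule.CLOSENESS, False)
        labels.append("L" if dl < dr else "R")
    return RuleResult(Rule.CLOSENESS, True, "".join(labels))


def connected_components(board: GameBoard) -> list[list[int]]:
    """Indices of circles grouped into 4-connected components.

    Two circles are connected when they sit on horizontally or vertically
    adjacent grid points (diagonal contact does not connect).
    """
    index = {p: i for i, p in enumerate(board.circles)}
    seen: set[int] = set()
    components = []
    for start in range(len(board.circles)):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            i = stack.pop()
            comp.append(i)
            x, y = board.circles[i]
            for nb in ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1)):
                j = index.get(nb)
                if j is not None and j not in seen:
                    seen.add(j)
                    stack.append(j)
        components.append(sorted(comp))
    return components


def accession_rule(board: GameBoard) -> RuleResult:
    """Assign each coherent circle group to its strictly nearer square."""
    labels = [""] * board.n_circles
    for comp in connected_components(board):
        dl = min(_sqdist(board.circles[i], board.square_left) for i in comp)
        dr = min(_sqdist(board.circles[i], board.square_right) for i in comp)
        if dl == dr:
            return RuleResult(Rule.ACCESSION, False)
        side = "L" if dl < dr else "R"
        for i in comp:
            labels[i] = side
    return RuleResult(Rule.ACCESSION, True, "".join(labels))


def equality_rule(board: GameBoard) -> RuleResult:
    """Split the circles in half with a vertical line, left half to the left square.

    Applicable iff the circle count is even and the n/2-th and (n/2+1)-th
    smallest x coordinates differ strictly (so a separating vertical line
    exists with no circle on it).  Because canonical circle order is x-major,
    the implied assignment is always ``"L" * (n//2) + "R" * (n//2)``.
    """
    n = board.n_circles
    if n % 2 != 0:
        return RuleResult(Rule.EQUALITY, False)
    xs = sorted(x for x, _ in board.circles)
    half = n // 2
    if xs[half - 1] >= xs[half]:
        return RuleResult(Rule.EQUALITY, False)
    return RuleResult(Rule.EQUALITY, True, "L" * half + "R" * half)


_RULE_FUNCS = {
    Rule.CLOSENESS: closeness_rule,
    Rule.EQUALITY: equality_rule,
    Rule.ACCESSION: accession_rule,
}


def evaluate_rule(rule: Rule, board: GameBoard) -> RuleResult:
    return _RULE_FUNCS[Rule(rule)](board)


def profile_board(board: GameBoard) -> BoardRuleProfile:
    """Evaluate all three selection rules on a board."""
    return BoardRuleProfile(
        board_id=board.board_id,
        results={rule: _RULE_FUNCS[rule](board) for rule in RULES},
    )
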