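"""Game boards, assignments, and response matrices for "Assign Circles" games.

An "Assign Circles" board is an integer grid holding two squares (one left,
one right) and a set of circles.  A player's answer to a board is a full
*assignment*: every circle is attached to exactly one square.  Assignments
are serialized as strings over ``{L, R}`` in the board's canonical circle
order — circles sorted left-to-right, ties broken top-to-bottom.

Coordinate convention: integer grid, origin at the top-left corner, ``x``
increasing rightward and ``y`` increasing downward.  Squares and circles
occupy single grid points (their cell centers).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

Point = tuple[int, int]

#: An assignment is a plain string over {L, R}; position i refers to the
#: i-th circle in canonical order.
Assignment = str


class BoardError(ValueError):
    """Raised when a board or assignment violates a structural invariant."""


def canonicalize_circles(points: Iterable[Sequence[int]]) -> list[Point]:
    """Sort circle positions into canonical order: ascending x, then ascending y.

    The ordering is total on distinct points, so the output is independent of
    the input permutation.  Duplicates are rejected.
    """
    pts = [(int(p[0]), int(p[1])) for p in points]
    if len(set(pts)) != len(pts):
        raise BoardError("duplicate circle positions")
    return sorted(pts)


@dataclass(frozen=True)
class GameBoard:
    """A two-square "Assign Circles" board on an integer grid.

    Circles are stored in canonical order (re-canonicalized on construction).
    """

    board_id: str
    grid_width: int
    grid_height: int
    circles: tuple[Point, ...]
    square_left: Point
    square_right: Point

    def __post_init__(self) -> None:
        circles = tuple(canonicalize_circles(self.circles))
        object.__setattr__(self, "circles", circles)
        sl = (int(self.square_left[0]), int(self.square_left[1]))
        sr = (int(self.square_right[0]), int(self.square_right[1]))
        object.__setattr__(self, "square_left", sl)
        object.__setattr__(self, "square_right", sr)
        if self.grid_width <= 0 or self.grid_height <= 0:
            raise BoardError(f"{self.board_id}: non-positive grid dimensions")
        if not sl[0] < sr[0]:
            raise BoardError(
                f"{self.board_id}: left square must be strictly left of right square"
            )
        if not circles:
            raise BoardError(f"{self.board_id}: board has no circles")
        for p in circles + (sl, sr):
            if not (0 <= p[0] < self.grid_width and 0 <= p[1] < self.grid_height):
                raise BoardError(f"{self.board_id}: point {p} outside grid")
        if set(circles) & {sl, sr}:
            raise BoardError(f"{self.board_id}: a circle coincides with a square")

    @property
    def n_circles(self) -> int:
        return len(self.circles)

    def translate(self, dx: int, dy: int) -> "GameBoard":
        """Return a copy of the board shifted by ``(dx, dy)`` on a grid large
        enough to contain it (used for invariance checks)."""
        pts = [(x + dx, y + dy) for x, y in self.circles]
        sl = (self.square_left[0] + dx, self.square_left[1] + dy)
        sr = (self.square_right[0] + dx, self.square_right[1] + dy)
        all_pts = pts + [sl, sr]
        w = max(x for x, _ in all_pts) + 1
        h = max(y for _, y in all_pts) + 1
        return GameBoard(self.board_id, w, h, tuple(pts), sl, sr)


def solution_space_size(board: GameBoard) -> int:
    """Number of full assignments on the board: 2 ** n_circles."""
    return 2 ** board.n_circles


def enumerate_assignments(n_circles: int) -> Iterator[Assignment]:
    """Yield all 2**n assignment strings in lexicographic (L < R) order."""
    for combo in itertools.product("LR", repeat=n_circles):
        yield "".join(combo)


def validate_assignment(assignment: Assignment, board: GameBoard) -> Assignment:
    """Check the assignment string against the board; return it unchanged."""
    if not isinstance(assignment, str):
        raise BoardError(f"assignment must be a string, got {type(assignment)!r}")
    if len(assignment) != board.n_circles:
        raise BoardError(
            f"assignment {assignment!r} has length {len(assignment)}, "
            f"board {board.board_id!r} has {board.n_circles} circles"
        )
    bad = set(assignment) - {"L", "R"}
    if bad:
        raise BoardError(f"assignment {assignment!r} contains invalid labels {bad}")
    return assignment


@dataclass
class ResponseMatrix:
    """Players x boards table of full assignments.

    The first ``n_predefined`` boards are the fixed layouts shown to every
    player; the remainder are the randomized fillers.  Individual
    coordination ability is computed on the predefined subset only, while
    strategy rates use all boards.
    """

    players: list[str]
    boards: list[GameBoard]
    choices: Mapping[tuple[str, str], Assignment]
    n_predefined: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_predefined == 0:
            self.n_predefined = len(self.boards)
        if not 0 < self.n_predefined <= len(self.boards):
            raise BoardError("n_predefined out of range")
        by_id = {b.board_id: b for b in self.boards}
        if len(by_id) != len(self.boards):
            raise BoardError("duplicate board_id in response matrix")
        for player in self.players:
            for board in self.boards:
                key = (player, board.board_id)
                if key not in self.choices:
                    raise BoardError(f"missing response for {key}")
                validate_assignment(self.choices[key], board)

    @property
    def n_players(self) -> int:
        return len(self.players)

    @property
    def predefined_boards(self) -> list[GameBoard]:
        return self.boards[: self.n_predefined]

    def column(self, board: GameBoard | str) -> list[Assignment]:
        """All players' assignments on one board, in player order."""
        bid = board if isinstance(board, str) else board.board_id
        return [self.choices[(p, bid)] for p in self.players]

    def to_frame(self) -> pd.DataFrame:
        """Players x boards DataFrame of assignment strings."""
        data = {
            b.board_id: [self.choices[(p, b.board_id)] for p in self.players]
            for b in self.boards
        }
        return pd.DataFrame(data, index=pd.Index(self.players, name="player"))


# ---------------------------------------------------------------------------
# I/O


def write_board(board: GameBoard, path: str | Path) -> None:
    payload = {
        "board_id": board.board_id,
        "grid": [board.grid_width, board.grid_height],
        "squares": {"left": list(board.square_left), "right": list(board.square_right)},
        "circles": [list(p) for p in board.circles],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_board(path: str | Path) -> GameBoard:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise BoardError(f"{path}: malformed board JSON: {exc}") from exc
    try:
        return GameBoard(
            board_id=str(payload["board_id"]),
            grid_width=int(payload["grid"][0]),
            grid_height=int(payload["grid"][1]),
            circles=tuple(tuple(p) for p in payload["circles"]),
            square_left=tuple(payload["squares"]["left"]),
            square_right=tuple(payload["squares"]["right"]),
        )
    except (KeyError, IndexError, TypeError) as exc:
        raise BoardError(f"{path}: missing or malformed field: {exc}") from exc


def write_responses(matrix: ResponseMatrix, path: str | Path) -> None:
    """Write the response matrix as CSV: one row per player, one column per board."""
    matrix.to_frame().to_csv(path)


def read_responses(
    path: str | Path, boards: Sequence[GameBoard], n_predefined: int | None = None
) -> ResponseMatrix:
    """Read a response CSV against a known list of boards.

    The CSV must have a ``player`` column followed by one column per board id;
    cells are L/R strings validated against each board's circle count.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str).set_index("player")
    expected = [b.board_id for b in boards]
    missing = set(expected) - set(frame.columns)
    if missing:
        raise BoardError(f"{path}: missing board columns {sorted(missing)}")
    players = list(frame.index)
    choices = {}
    for board in boards:
        for player, cell in frame[board.board_id].items():
            if not isinstance(cell, str):
                raise BoardError(
                    f"{path}: empty cell for player {player!r}, board {board.board_id!r}"
                )
            choices[(player, board.board_id)] = cell
    return ResponseMatrix(
        players=players,
        boards=list(boards),
        choices=choices,
        n_predefined=n_predefined or len(boards),
    )
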