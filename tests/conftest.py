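import numpy as np
import pytest

from tacitcoord import GameBoard, ResponseMatrix


@pytest.fixture(scope="session")
def two_circle_board() -> GameBoard:
    """Symmetric easy board: both circles strictly nearer one square each."""
    return GameBoard("b2", 10, 5, ((2, 2), (7, 2)), (1, 2), (8, 2))


@pytest.fixture(scope="session")
def one_circle_board() -> GameBoard:
    """Single circle equidistant from both squares: no rule applies."""
    return GameBoard("b1", 10, 6, ((5, 4),), (2, 2), (8, 2))


@pytest.fixture()
def tiny_matrix(two_circle_board, one_circle_board) -> ResponseMatrix:
    """Hand-built 3-player cohort used for hand-checked score values."""
    choices = {
        ("p1", "b2"): "LR", ("p1", "b1"): "L",
        ("p2", "b2"): "LR", ("p2", "b1"): "R",
        ("p3", "b2"): "RL", ("p3", "b1"): "L",
    }
    return ResponseMatrix(
        players=["p1", "p2", "p3"],
        boards=[two_circle_board, one_circle_board],
        choices=choices,
        n_predefined=2,
    )


def random_board(rng: np.random.Generator, n_circles: int, w: int = 10, h: int = 6) -> GameBoard:
    """Uniform random valid board for oracle fuzzing."""
    left = (int(rng.integers(0, w // 2 - 1)), int(rng.integers(0, h)))
    right = (int(rng.integers(w // 2 + 1, w)), int(rng.integers(0, h)))
    cells = [(x, y) for x in range(w) for y in range(h) if (x, y) not in (left, right)]
    idx = rng.choice(len(cells), size=n_circles, replace=False)
    return GameBoard("rand", w, h, tuple(cells[i] for i in idx), left, right)
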