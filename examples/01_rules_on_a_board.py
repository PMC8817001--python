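"""Evaluate the three selection rules on a small board.

Builds a 3-circle board with a coherent pair of circles near the left
square, prints each rule's applicability and implied assignment, and the
set of predicted responses (the solutions a rule-guided player might give).
"""

from tacitcoord import GameBoard, profile_board

board = GameBoard(
    board_id="demo",
    grid_width=10,
    grid_height=5,
    circles=((2, 1), (2, 2), (8, 2)),
    square_left=(1, 2),
    square_right=(9, 2),
)

profile = profile_board(board)
print(f"board {board.board_id}: {board.n_circles} circles")
for rule, result in profile.results.items():
    implied = result.assignment if result.applicable else "(not applicable)"
    print(f"  {rule.value:10s} -> {implied}")
print("predicted responses:", sorted(profile.predicted_responses))
# The L/R string lists circles left-to-right (ties top-to-bottom): here the
# adjacent pair goes to the left square and the far circle to the right one;
# equality needs an even circle count, so it cannot apply.
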