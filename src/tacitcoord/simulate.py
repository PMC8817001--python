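"""Synthetic boards and agent populations for tacit coordination experiments.

The original behavioral dataset is not redistributable, so every pipeline
stage is exercised on simulated cohorts instead.  An agent is a two-level
mixture: with probability ``noise`` it picks a full assignment uniformly at
random from the solution space; otherwise it samples among the assignments
implied by the applicable selection rules, with probability proportional to
the summed propensity weights of the rules implying each assignment (rules
that imply the same string pool their mass).  When no rule applies, the
agent also picks uniformly.

The default population emulates the emulated study's structure: 93 agents
playing 10 fixed boards plus 4 randomly generated ones, in three ability
strata (two tight low-noise strata and one broad high-noise stratum) with
rule propensities favoring closeness and equality over accession.  This
yields multimodal ability-score distributions and strategy-rate profiles
correlated with ability.

The ten fixed boards are synthetic reconstructions: their exact historical
coordinates are not published, so layouts were designed to reproduce the
documented per-board pattern of rule applicability and implied assignments
(including circle counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .boards import Assignment, GameBoard, ResponseMatrix, enumerate_assignments
from .rules import RULES, BoardRuleProfile, Rule, profile_board

__all__ = [
    "AgentSpec",
    "StratumSpec",
    "PopulationSpec",
    "reference_boards",
    "generate_board",
    "simulate_agent",
    "simulate_population",
    "default_population",
]


@dataclass(frozen=True)
class AgentSpec:
    """Propensity weights over the three selection rules plus choice noise."""

    w_closeness: float
    w_equality: float
    w_accession: float
    noise: float
    agent_id: str = ""

    def __post_init__(self) -> None:
        ws = (self.w_closeness, self.w_equality, self.w_accession)
        if any(w < 0 for w in ws):
            raise ValueError("propensity weights must be non-negative")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must lie in [0, 1]")
        if sum(ws) == 0 and self.noise < 1.0:
            raise ValueError("all-zero propensities require noise = 1")

    @property
    def weights(self) -> dict[Rule, float]:
        return {
            Rule.CLOSENESS: self.w_closeness,
            Rule.EQUALITY: self.w_equality,
            Rule.ACCESSION: self.w_accession,
        }


def reference_boards() -> list[GameBoard]:
    """Ten synthetic fixed boards mirroring the documented rule patterns.

    Per board (closeness / accession / equality implied assignments; "-" =
    inapplicable):

    ==  =======  =======  =====
    g1  LR       LR       LR
    g2  LLRR     LLRR     LLRR
    g3  -        LLR      -
    g4  -        -        LLRR
    g5  LLR      LLR      -
    g6  -        LRRR     LLRR
    g7  -        -        -
    g8  -        -        -
    g9  LRRR     LRRR     LLRR
    g10 LLRRR    LLLRR    -
    ==  =======  =======  =====
    """
    b = GameBoard
    return [
        b("g01", 10, 5, ((2, 2), (7, 2)), (1, 2), (8, 2)),
        b("g02", 12, 5, ((2, 1), (2, 3), (9, 1), (9, 3)), (1, 2), (10, 2)),
        b("g03", 10, 7, ((4, 5), (5, 5), (6, 1)), (2, 3), (8, 3)),
        b("g04", 12, 9, ((3, 7), (5, 4), (7, 1), (9, 5)), (2, 2), (8, 6)),
        b("g05", 10, 5, ((2, 1), (2, 2), (8, 2)), (1, 2), (9, 2)),
        b("g06", 11, 7, ((2, 3), (5, 3), (6, 3), (7, 3)), (1, 3), (9, 3)),
        b("g07", 10, 6, ((5, 4),), (2, 2), (8, 2)),
        b("g08", 10, 5, ((5, 1), (5, 3)), (2, 2), (8, 2)),
        b("g09", 10, 7, ((2, 5), (4, 1), (6, 2), (8, 2)), (1, 5), (7, 1)),
        b("g10", 12, 6, ((4, 4), (5, 4), (6, 4), (8, 2), (8, 3)), (1, 4), (10, 4)),
    ]


def generate_board(
    n_circles: int,
    grid: tuple[int, int] = (12, 8),
    seed: int | np.random.Generator | None = None,
    constraints: Optional[Mapping[Rule, bool]] = None,
    board_id: str = "random",
    max_tries: int = 2000,
) -> GameBoard:
    """Sample a random valid board, optionally forcing rule applicability.

    ``constraints`` maps rules to required applicability (True/False);
    rejection sampling with a retry cap.  The two squares sit at fixed
    mid-height positions near the grid edges; circles land anywhere else.
    """
    w, h = grid
    if w < 4 or h < 1 or n_circles > w * h - 2:
        raise ValueError("grid too small for the requested circles + squares")
    rng = np.random.default_rng(seed)
    square_left = (1, h // 2)
    square_right = (w - 2, h // 2)
    free = [
        (x, y)
        for x in range(w)
        for y in range(h)
        if (x, y) not in (square_left, square_right)
    ]
    for _ in range(max_tries):
        idx = rng.choice(len(free), size=n_circles, replace=False)
        circles = tuple(free[i] for i in idx)
        board = GameBoard(board_id, w, h, circles, square_left, square_right)
        if constraints:
            prof = profile_board(board)
            if any(
                prof[Rule(r)].applicable != want for r, want in constraints.items()
            ):
                continue
        return board
    raise RuntimeError(
        f"could not satisfy constraints {constraints} in {max_tries} tries"
    )


def simulate_agent(
    agent: AgentSpec,
    board: GameBoard,
    seed: int | np.random.Generator | None = None,
    profile: Optional[BoardRuleProfile] = None,
) -> Assignment:
    """One agent's choice on one board (see module docstring for the model)."""
    rng = np.random.default_rng(seed)
    if rng.random() >= agent.noise:
        prof = profile if profile is not None else profile_board(board)
        pooled: dict[Assignment, float] = {}
        for rule in RULES:
            res = prof[rule]
            if res.applicable:
                weight = agent.weights[rule]
                if weight > 0:
                    pooled[res.assignment] = pooled.get(res.assignment, 0.0) + weight
        if pooled:
            options = sorted(pooled)
            probs = np.array([pooled[o] for o in options])
            return options[rng.choice(len(options), p=probs / probs.sum())]
    # noise draw, or no applicable rule with positive propensity: uniform
    n = board.n_circles
    bits = rng.integers(0, 2, size=n)
    return "".join("LR"[b] for b in bits)


@dataclass(frozen=True)
class StratumSpec:
    """One ability stratum: share of agents plus noise and propensity laws.

    ``noise_low``/``noise_high`` bound a uniform draw of per-agent noise;
    ``propensity_alpha`` parameterizes a Dirichlet over the rule weights
    (order: closeness, equality, accession).
    """

    fraction: float
    noise_low: float
    noise_high: float
    propensity_alpha: tuple[float, float, float] = (4.0, 4.0, 2.0)


#: Three strata shaped like the emulated ability distribution: two tight
#: high-ability modes and one broad low-ability component.
DEFAULT_STRATA = (
    StratumSpec(fraction=0.30, noise_low=0.02, noise_high=0.08),
    StratumSpec(fraction=0.40, noise_low=0.18, noise_high=0.28),
    StratumSpec(fraction=0.30, noise_low=0.45, noise_high=0.95),
)


@dataclass
class PopulationSpec:
    """A simulated cohort: boards, agents, and the master seed."""

    n_agents: int
    boards: list[GameBoard]
    n_predefined: int
    agents: Optional[list[AgentSpec]] = None
    strata: Sequence[StratumSpec] = field(default_factory=lambda: DEFAULT_STRATA)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("need at least 2 agents")
        if not 1 <= self.n_predefined <= len(self.boards):
            raise ValueError("n_predefined out of range")
        if self.agents is not None and len(self.agents) != self.n_agents:
            raise ValueError("agents list length must equal n_agents")


def _draw_agents(spec: PopulationSpec, rng: np.random.Generator) -> list[AgentSpec]:
    fractions = np.array([s.fraction for s in spec.strata], dtype=float)
    fractions = fractions / fractions.sum()
    counts = np.floor(fractions * spec.n_agents).astype(int)
    while counts.sum() < spec.n_agents:
        counts[int(np.argmax(fractions * spec.n_agents - counts))] += 1
    agents = []
    i = 0
    for stratum, count in zip(spec.strata, counts):
        for _ in range(count):
            noise = float(rng.uniform(stratum.noise_low, stratum.noise_high))
            w = rng.dirichlet(stratum.propensity_alpha)
            agents.append(
                AgentSpec(
                    w_closeness=float(w[0]),
                    w_equality=float(w[1]),
                    w_accession=float(w[2]),
                    noise=noise,
                    agent_id=f"p{i:03d}",
                )
            )
            i += 1
    return agents


def simulate_population(spec: PopulationSpec) -> ResponseMatrix:
    """Simulate the full response matrix of a cohort.

    The master seed is split into independent per-agent streams, so any
    agent's choices can be regenerated without replaying the others.
    """
    root = np.random.SeedSequence(spec.seed)
    agent_seed, *_ = root.spawn(1)
    rng = np.random.default_rng(agent_seed)
    agents = spec.agents if spec.agents is not None else _draw_agents(spec, rng)
    profiles = {b.board_id: profile_board(b) for b in spec.boards}
    choices: dict[tuple[str, str], Assignment] = {}
    streams = root.spawn(len(agents) + 1)[1:]
    players = []
    for agent, stream in zip(agents, streams):
        player = agent.agent_id or f"p{len(players):03d}"
        players.append(player)
        agent_rng = np.random.default_rng(stream)
        for board in spec.boards:
            choices[(player, board.board_id)] = simulate_agent(
                agent, board, seed=agent_rng, profile=profiles[board.board_id]
            )
    return ResponseMatrix(
        players=players,
        boards=list(spec.boards),
        choices=choices,
        n_predefined=spec.n_predefined,
    )


def default_population(
    n_agents: int = 93,
    seed: int = 0,
    n_random_boards: int = 4,
    strata: Sequence[StratumSpec] = DEFAULT_STRATA,
) -> PopulationSpec:
    """The emulated study design: 93 agents, 10 fixed + 4 random boards."""
    boards = reference_boards()
    board_rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB0A2D)))
    for i in range(n_random_boards):
        n_circles = int(board_rng.integers(2, 7))
        boards.append(
            generate_board(
                n_circles, seed=board_rng, board_id=f"r{i + 1:02d}"
            )
        )
    return PopulationSpec(
        n_agents=n_agents,
        boards=boards,
        n_predefined=len(reference_boards()),
        strata=strata,
        seed=seed,
    )
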