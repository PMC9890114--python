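"""Scripted stand-ins for human participants of graded skill.

Three policy families form a skill ladder: uniform-random play, coin-greedy
play, and standard-reward MCTS whose strength scales with its iteration
budget. Participant heterogeneity in simulated studies is modelled by
sampling specs from a configured pool (budgets log-spaced by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import GameState, Move, Phase, legal_actions
from .errors import ConfigurationError, PolicyError
from .mcts import SearchConfig, search
from .rewards import standard_spec

POLICIES = ("random", "greedy", "mcts_standard")


@dataclass(frozen=True)
class OpponentSpec:
    """A scripted participant: policy family, budget (MCTS only), seed."""

    policy: str = "greedy"
    budget: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.policy not in POLICIES:
            raise ConfigurationError(
                f"unknown policy {self.policy!r}; expected one of {POLICIES}")
        if self.policy == "mcts_standard" and self.budget < 1:
            raise ConfigurationError("mcts_standard requires budget >= 1")

    def to_dict(self) -> dict:
        return {"policy": self.policy, "budget": self.budget, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "OpponentSpec":
        return cls(**d)


def _actions_or_raise(state: GameState) -> list[Move]:
    if state.is_terminal:
        raise PolicyError("no legal action in a terminal state")
    acts = legal_actions(state)
    if not acts:
        raise PolicyError("no legal action available")
    return acts


def random_policy(state: GameState, rng: np.random.Generator) -> Move:
    """Uniform over all legal actions."""
    acts = _actions_or_raise(state)
    return acts[int(rng.integers(len(acts)))]


def greedy_policy(state: GameState, rng: np.random.Generator) -> Move:
    """Slide to the destination with the most coins (ties uniform);
    placements are chosen uniformly."""
    acts = _actions_or_raise(state)
    if state.phase == Phase.PLACEMENT:
        return acts[int(rng.integers(len(acts)))]
    coins = state.board.coins
    gains = [int(coins[m.to.row * state.cols + m.to.col]) for m in acts]
    best = max(gains)
    tied = [m for m, g in zip(acts, gains) if g == best]
    return tied[int(rng.integers(len(tied)))]


def mcts_standard_policy(state: GameState, budget: int,
                         rng: np.random.Generator) -> Move:
    """Play-to-win MCTS at the given iteration budget (searches as the
    player to move, with the standard reward on its own side)."""
    _actions_or_raise(state)
    cfg = SearchConfig(iterations=budget, seed=int(rng.integers(2 ** 31)))
    return search(state, cfg, standard_spec())


def act(spec: OpponentSpec, state: GameState, rng: np.random.Generator) -> Move:
    """Dispatch one move of the scripted participant `spec`."""
    if spec.policy == "random":
        return random_policy(state, rng)
    if spec.policy == "greedy":
        return greedy_policy(state, rng)
    return mcts_standard_policy(state, spec.budget, rng)


def default_pool(budgets: tuple[int, ...] = (100, 300, 1000)) -> list[OpponentSpec]:
    """A heterogeneous participant pool: random, greedy and log-spaced
    MCTS budgets."""
    pool = [OpponentSpec("random"), OpponentSpec("greedy")]
    pool += [OpponentSpec("mcts_standard", budget=b) for b in budgets]
    return pool
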