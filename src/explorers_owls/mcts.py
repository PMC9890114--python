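"""Monte Carlo Tree Search over :class:`~explorers_owls.engine.GameState`.

Four phases per iteration: *selection* descends from the root by an urgency
rule (UCB1) until reaching a node with untried moves or a terminal node;
*expansion* adds one random untried child; *simulation* plays uniformly
random moves to the end of the game; *backpropagation* adds the terminal
reward pair to every node on the path.

Rewards are per-player pairs (participant, AI); at each node the urgency and
the final move selection use the component belonging to the player to move
at the parent, so the search models the participant as playing to win even
when the AI itself pursues an outcome target.

Two interchangeable engines implement the identical algorithm:

* ``"compiled"`` (default) — the numba kernel in :mod:`._core`; used for
  real budgets (thousands of iterations per move).
* ``"python"`` — an explicit :class:`SearchNode` tree via
  :func:`run_iteration`; inspectable, used by tests and for custom reward
  callables.

The two engines draw from different random streams, so they agree on forced
or clearly best moves but not playout-by-playout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import _core
from .engine import GameState, Move, Player, _gen_raw, _move_from_row
from .errors import ConfigurationError, SearchError
from .rewards import RewardSpec, terminal_reward_pair

FINAL_SELECTIONS = ("max_mean_reward", "max_visits")


@dataclass(frozen=True)
class SearchConfig:
    """Search budget and selection parameters.

    iterations: playouts per move decision (default 7500, strong play at
        acceptable per-move latency on the standard board).
    exploration_constant: UCB1 exploration weight c (default sqrt(2)).
    seed: RNG seed for expansion order, playouts and tie-breaks.
    final_selection: root-move criterion, mean reward (default) or visits.
    """

    iterations: int = 7500
    exploration_constant: float = math.sqrt(2.0)
    seed: int = 0
    final_selection: str = "max_mean_reward"

    def __post_init__(self):
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")
        if self.exploration_constant < 0:
            raise ConfigurationError("exploration_constant must be >= 0")
        if self.final_selection not in FINAL_SELECTIONS:
            raise ConfigurationError(
                f"final_selection must be one of {FINAL_SELECTIONS}")

    def to_dict(self) -> dict:
        return {"iterations": self.iterations,
                "exploration_constant": self.exploration_constant,
                "seed": self.seed, "final_selection": self.final_selection}

    @classmethod
    def from_dict(cls, d: dict) -> "SearchConfig":
        return cls(**d)


@dataclass
class SearchNode:
    """One node of the explicit (python-engine) search tree."""

    state: GameState
    incoming_move: Optional[Move] = None
    parent: Optional["SearchNode"] = None
    children: list["SearchNode"] = field(default_factory=list)
    untried_moves: list[Move] = field(default_factory=list)
    visits: int = 0
    total_reward: np.ndarray = field(default_factory=lambda: np.zeros(2))
    player_to_move: Player = Player.PARTICIPANT

    @classmethod
    def root(cls, state: GameState) -> "SearchNode":
        from .engine import legal_actions
        untried = [] if state.is_terminal else legal_actions(state)
        return cls(state=state, untried_moves=untried,
                   player_to_move=state.to_move)

    @property
    def is_terminal(self) -> bool:
        return self.state.is_terminal

    def mean_reward(self, player: Player) -> float:
        return float(self.total_reward[int(player)]) / self.visits


def urgency(child: SearchNode, parent: SearchNode, c: float) -> float:
    """UCB1 urgency of `child` from `parent`'s point of view.

    Unvisited children score +inf so each is explored once before any is
    revisited; otherwise mean reward for the player to move at the parent
    plus ``c * sqrt(ln(parent.visits) / child.visits)``.
    """
    if child.visits == 0:
        return math.inf
    exploit = child.mean_reward(parent.player_to_move)
    return exploit + c * math.sqrt(math.log(parent.visits) / child.visits)


def _random_playout(state: GameState, rng: np.random.Generator) -> GameState:
    """Uniform-random playout at array level (no history tracking)."""
    s = state.copy_array()
    rows, cols, k = state.rows, state.cols, state.figures_per_player
    buf = np.zeros((_core.max_moves(rows, cols, k), 4), np.int16)
    b = 4 * rows * cols + 2 * k
    while s[b + 2] != _core.PHASE_TERMINAL:
        n = _core.gen_moves(s, rows, cols, k, s[b + 3], buf)
        if n == 0:
            raise SearchError("non-terminal state with no legal moves")
        j = int(rng.integers(n))
        _core.apply_move(s, rows, cols, k, buf[j, 0], buf[j, 1], buf[j, 2], buf[j, 3])
    return GameState(s, rows, cols, k)


def run_iteration(root: SearchNode,
                  reward_fn: Callable[[GameState], tuple[float, float]],
                  rng: np.random.Generator,
                  c: float = math.sqrt(2.0)) -> None:
    """One selection/expansion/simulation/backpropagation pass (in place)."""
    if root.is_terminal:
        raise SearchError("cannot search a terminal state")
    from .engine import apply_move, legal_actions

    node = root
    # selection
    while not node.is_terminal and not node.untried_moves and node.children:
        node = max(node.children, key=lambda ch: urgency(ch, node, c))
    # expansion
    if not node.is_terminal and node.untried_moves:
        j = int(rng.integers(len(node.untried_moves)))
        move = node.untried_moves.pop(j)
        child_state = apply_move(node.state, move)
        child = SearchNode(
            state=child_state, incoming_move=move, parent=node,
            untried_moves=[] if child_state.is_terminal else legal_actions(child_state),
            player_to_move=child_state.to_move)
        node.children.append(child)
        node = child
    # simulation
    terminal = node.state if node.is_terminal else _random_playout(node.state, rng)
    rp, ra = reward_fn(terminal)
    # backpropagation
    cur: Optional[SearchNode] = node
    while cur is not None:
        cur.visits += 1
        cur.total_reward[0] += rp
        cur.total_reward[1] += ra
        cur = cur.parent


def _select_best(children, player: Player, final_selection: str,
                 rng: np.random.Generator):
    def score(ch):
        if final_selection == "max_visits":
            return float(ch.visits)
        return ch.mean_reward(player)

    best = max(score(ch) for ch in children)
    tied = [ch for ch in children if score(ch) >= best - 1e-12]
    if len(tied) > 1:
        top_visits = max(ch.visits for ch in tied)
        tied = [ch for ch in tied if ch.visits == top_visits]
    if len(tied) > 1:
        return tied[int(rng.integers(len(tied)))]
    return tied[0]


def search_python(state: GameState, config: SearchConfig,
                  reward, return_stats: bool = False):
    """Explicit-tree search; `reward` is a RewardSpec or a custom callable
    mapping a terminal GameState to a (participant, AI) reward pair."""
    if state.is_terminal:
        raise SearchError("cannot search a terminal state")
    reward_fn = terminal_reward_pair(reward) if isinstance(reward, RewardSpec) else reward
    rng = np.random.default_rng(config.seed)
    root = SearchNode.root(state)
    if not root.untried_moves:
        raise SearchError("no legal moves at the search root")
    for _ in range(config.iterations):
        run_iteration(root, reward_fn, rng, c=config.exploration_constant)
    best = _select_best(root.children, root.player_to_move,
                        config.final_selection, rng)
    if not return_stats:
        return best.incoming_move
    return best.incoming_move, tree_stats(root)


def search_compiled(state: GameState, config: SearchConfig, reward: RewardSpec,
                    return_stats: bool = False):
    if state.is_terminal:
        raise SearchError("cannot search a terminal state")
    if not isinstance(reward, RewardSpec):
        raise ConfigurationError("the compiled engine requires a RewardSpec")
    if len(_gen_raw(state, state.to_move)) == 0:
        raise SearchError("no legal moves at the search root")
    rows, cols, k = state.rows, state.cols, state.figures_per_player
    target = reward.target_pwm if reward.mode != "standard" else 0
    best, cmoves, cvisits, cmean, root_visits = _core.mcts_search(
        state._s, rows, cols, k, config.iterations,
        float(config.exploration_constant), int(config.seed) % (2 ** 31),
        reward.mode_code, target, reward.max_move_score, float(reward.span),
        float(reward.draw_reward),
        0 if config.final_selection == "max_mean_reward" else 1,
        _core.max_moves(rows, cols, k))
    move = _move_from_row(state, best)
    if not return_stats:
        return move
    stats = {
        "root_visits": int(root_visits),
        "player": state.to_move.name,
        "children": [
            {"move": _move_dict(_move_from_row(state, cmoves[i])),
             "visits": int(cvisits[i]),
             "mean_reward": [float(cmean[i, 0]), float(cmean[i, 1])]}
            for i in range(len(cvisits))
        ],
    }
    return move, stats


def search(state: GameState, config: SearchConfig, reward,
           engine: str = "compiled", return_stats: bool = False):
    """Run `config.iterations` MCTS iterations and return the chosen Move.

    The root child maximising the configured final-selection criterion (for
    the searching player) is returned; ties break to higher visit counts,
    then a seeded random pick. Deterministic given state, config and seed
    (per engine).
    """
    if engine == "compiled" and isinstance(reward, RewardSpec):
        return search_compiled(state, config, reward, return_stats)
    if engine not in ("compiled", "python"):
        raise ConfigurationError(f"unknown search engine {engine!r}")
    return search_python(state, config, reward, return_stats)


def _move_dict(move: Move) -> dict:
    return {
        "kind": move.kind.value,
        "figure": move.figure,
        "from": None if move.frm is None else [move.frm.col, move.frm.row],
        "to": [move.to.col, move.to.row],
    }


def tree_stats(root: SearchNode) -> dict:
    """JSON-ready per-root-child statistics (the documented tree dump)."""
    return {
        "root_visits": root.visits,
        "player": root.player_to_move.name,
        "children": [
            {"move": _move_dict(ch.incoming_move),
             "visits": ch.visits,
             "mean_reward": [float(ch.total_reward[0] / max(ch.visits, 1)),
                             float(ch.total_reward[1] / max(ch.visits, 1))]}
            for ch in root.children
        ],
    }
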