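"""Exhaustive game-tree evaluation for tiny boards.

Backward-induction (minimax) oracles used to verify search behaviour and to
certify fixture positions. Tractable only for small positions (roughly ten
open tiles and one figure per player); the full game is far beyond
exhaustive search, which is the point of MCTS.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from . import _core
from .engine import GameState, Move, _move_from_row
from .errors import SearchError


def _successors(s: np.ndarray, rows: int, cols: int, k: int, buf: np.ndarray):
    b = 4 * rows * cols + 2 * k
    n = _core.gen_moves(s, rows, cols, k, s[b + 3], buf)
    moves = buf[:n].copy()  # recursion below reuses buf; detach first
    for j in range(n):
        s2 = s.copy()
        _core.apply_move(s2, rows, cols, k,
                         moves[j, 0], moves[j, 1], moves[j, 2], moves[j, 3])
        yield moves[j], s2


def exact_margin(state: GameState) -> int:
    """Final PWM under optimal play: the participant maximises the margin,
    the AI minimises it (zero-sum on participant score − AI score)."""
    rows, cols, k = state.rows, state.cols, state.figures_per_player
    b = 4 * rows * cols + 2 * k
    buf = np.zeros((_core.max_moves(rows, cols, k), 4), np.int16)

    @lru_cache(maxsize=None)
    def value(key: bytes) -> int:
        s = np.frombuffer(key, dtype=np.int16).copy()
        if s[b + 2] == _core.PHASE_TERMINAL:
            return int(s[b]) - int(s[b + 1])
        vals = [value(s2.tobytes()) for _, s2 in _successors(s, rows, cols, k, buf)]
        if not vals:
            raise SearchError("non-terminal state with no moves")
        return max(vals) if s[b + 3] == 0 else min(vals)

    return value(state._s.tobytes())


def exact_values(state: GameState) -> list[tuple[Move, int]]:
    """(move, optimal final margin after the move) for every legal move."""
    rows, cols, k = state.rows, state.cols, state.figures_per_player
    buf = np.zeros((_core.max_moves(rows, cols, k), 4), np.int16)
    out = []
    for row, s2 in _successors(state._s.copy(), rows, cols, k, buf):
        child = GameState(s2, rows, cols, k)
        out.append((_move_from_row(state, row), exact_margin(child)))
    return out


def margin_to_standard_reward(margin: int, draw_reward: float = 0.5,
                              for_player: int = 1) -> float:
    """Map an optimal margin to the standard win/draw/loss reward of a side
    (1 = AI, 0 = participant)."""
    if margin == 0:
        return draw_reward
    ai_wins = margin < 0
    win = ai_wins if for_player == 1 else not ai_wins
    return 1.0 if win else 0.0


def exact_standard_values(state: GameState, draw_reward: float = 0.5) -> list[tuple[Move, float]]:
    """(move, exact game-theoretic standard reward for the mover) per move.

    Optimality is judged on the win/draw/loss outcome itself, not the
    margin, so the game value is recomputed on the reward scale. With the
    symmetric draw value 0.5 the game is zero-sum (participant reward =
    1 − AI reward); other draw values are not supported here.
    """
    rows, cols, k = state.rows, state.cols, state.figures_per_player
    b = 4 * rows * cols + 2 * k
    buf = np.zeros((_core.max_moves(rows, cols, k), 4), np.int16)
    mover = int(state._s[b + 3])

    @lru_cache(maxsize=None)
    def value(key: bytes) -> float:
        # game value on the AI-reward scale (participant minimises)
        s = np.frombuffer(key, dtype=np.int16).copy()
        if s[b + 2] == _core.PHASE_TERMINAL:
            margin = int(s[b]) - int(s[b + 1])
            return margin_to_standard_reward(margin, draw_reward, for_player=1)
        vals = [value(s2.tobytes()) for _, s2 in _successors(s, rows, cols, k, buf)]
        return max(vals) if s[b + 3] == 1 else min(vals)

    out = []
    for row, s2 in _successors(state._s.copy(), rows, cols, k, buf):
        v_ai = value(s2.tobytes())
        v = v_ai if mover == 1 else 1.0 - v_ai
        out.append((_move_from_row(state, row), v))
    return out
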