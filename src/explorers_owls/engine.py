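"""Deterministic rules engine for *Explorers vs Owls*.

A two-player, perfect-information, turn-based game on a hex grid. Every tile
holds 1-3 coins. Players first alternate placing their figures on one-coin
tiles (participant first), then alternate sliding a figure in a straight hex
line. Sliding off a tile turns it to lava forever; arriving on a tile scores
its coins for the mover. A figure that cannot slide is removed (its tile
becomes lava, its coins are forfeited). The game ends when all figures are
gone; the higher coin total wins.

Coordinates use the "odd-r" horizontal offset layout (odd rows shifted half
a tile right), mapped to axial coordinates for straight-line geometry. The
standard game is 7x7 with three figures per player and 81 coins in total, so
the final score margin (PWM, participant minus AI) always lies in [-81, 81].

States are immutable from the caller's point of view: :func:`apply_move`
returns a new :class:`GameState`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Iterable, Mapping, Optional

import numpy as np

from . import _core
from .errors import ConfigurationError, IllegalMoveError, PhaseError

STANDARD_ROWS = 7
STANDARD_COLS = 7
STANDARD_FIGURES = 3
#: Default per-board coin mix: 26+14+9 = 49 tiles, 26+28+27 = 81 coins.
STANDARD_COIN_COUNTS = {1: 26, 2: 14, 3: 9}

TUTORIAL_ROWS = 4
TUTORIAL_COLS = 4
TUTORIAL_FIGURES = 1
TUTORIAL_COIN_COUNTS = {1: 10, 2: 4, 3: 2}


class Player(IntEnum):
    PARTICIPANT = 0
    AI = 1

    @property
    def other(self) -> "Player":
        return Player(1 - self.value)


class Phase(IntEnum):
    PLACEMENT = 0
    MOVEMENT = 1
    TERMINAL = 2


class MoveKind(Enum):
    PLACE = "place"
    SLIDE = "slide"


class Result(Enum):
    PLAYER_WIN = "player_win"
    DRAW = "draw"
    PLAYER_LOSS = "player_loss"


@dataclass(frozen=True, order=True)
class HexCoord:
    """Offset (odd-r) hex coordinate; `col`/`row` are 0-based grid indices."""

    col: int
    row: int

    def to_axial(self) -> tuple[int, int]:
        return self.col - (self.row - (self.row & 1)) // 2, self.row


@dataclass(frozen=True)
class Move:
    kind: MoveKind
    figure: int
    frm: Optional[HexCoord]
    to: HexCoord


@dataclass(frozen=True)
class Tile:
    coins: int
    lava: bool
    scored: bool

    @property
    def state(self) -> str:
        return "lava" if self.lava else "open"


@dataclass(frozen=True)
class Figure:
    owner: Player
    index: int
    position: Optional[HexCoord]
    alive: bool


class Board:
    """An immutable initial tile layout (no lava, no figures)."""

    def __init__(self, rows: int, cols: int, coins: np.ndarray, seed: Optional[int] = None):
        coins = np.asarray(coins, dtype=np.int16)
        if coins.shape != (rows * cols,):
            raise ConfigurationError(
                f"coin array has {coins.size} entries for a {rows}x{cols} board")
        if not np.all((coins >= 1) & (coins <= 3)):
            raise ConfigurationError("tile coin values must lie in {1, 2, 3}")
        self.rows = int(rows)
        self.cols = int(cols)
        self.seed = seed
        self._coins = coins
        self._coins.setflags(write=False)

    @property
    def coins(self) -> np.ndarray:
        return self._coins

    @property
    def total_coins(self) -> int:
        return int(self._coins.sum())

    @property
    def tiles(self) -> dict[HexCoord, Tile]:
        return {
            HexCoord(i % self.cols, i // self.cols): Tile(int(c), False, False)
            for i, c in enumerate(self._coins)
        }

    def __eq__(self, other) -> bool:
        return (isinstance(other, Board) and self.rows == other.rows
                and self.cols == other.cols
                and bool(np.array_equal(self._coins, other._coins)))

    def __repr__(self) -> str:
        return f"Board({self.rows}x{self.cols}, total_coins={self.total_coins})"


def generate_board(rows: int, cols: int, coin_counts: Mapping[int, int],
                   seed: int, figures_per_player: int = STANDARD_FIGURES) -> Board:
    """Generate a board whose tile coin multiset matches `coin_counts`,
    shuffled by a seeded generator. Identical arguments give identical boards.
    """
    if not set(coin_counts) <= {1, 2, 3}:
        raise ConfigurationError(f"coin values must be in {{1,2,3}}, got {sorted(coin_counts)}")
    total_tiles = sum(coin_counts.values())
    if total_tiles != rows * cols:
        raise ConfigurationError(
            f"coin counts cover {total_tiles} tiles but the grid has {rows * cols}")
    if coin_counts.get(1, 0) < 2 * figures_per_player:
        raise ConfigurationError(
            f"need at least {2 * figures_per_player} one-coin tiles for placement, "
            f"got {coin_counts.get(1, 0)}")
    values = np.concatenate([
        np.full(n, v, dtype=np.int16) for v, n in sorted(coin_counts.items())
    ])
    rng = np.random.default_rng(seed)
    rng.shuffle(values)
    return Board(rows, cols, values, seed=seed)


def standard_board(seed: int) -> Board:
    return generate_board(STANDARD_ROWS, STANDARD_COLS, STANDARD_COIN_COUNTS,
                          seed, STANDARD_FIGURES)


def tutorial_board(seed: int) -> Board:
    return generate_board(TUTORIAL_ROWS, TUTORIAL_COLS, TUTORIAL_COIN_COUNTS,
                          seed, TUTORIAL_FIGURES)


class GameState:
    """A full game position, backed by the compiled kernels' flat array."""

    __slots__ = ("_s", "rows", "cols", "figures_per_player", "move_history")

    def __init__(self, s: np.ndarray, rows: int, cols: int, figures_per_player: int,
                 move_history: tuple[Move, ...] = ()):
        self._s = s
        self.rows = rows
        self.cols = cols
        self.figures_per_player = figures_per_player
        self.move_history = move_history

    # -- construction -----------------------------------------------------

    @classmethod
    def new(cls, board: Board, figures_per_player: int = STANDARD_FIGURES) -> "GameState":
        n = board.rows * board.cols
        if int((board.coins == 1).sum()) < 2 * figures_per_player:
            raise ConfigurationError("too few one-coin tiles for placement")
        s = np.zeros(_core.state_size(board.rows, board.cols, figures_per_player),
                     dtype=np.int16)
        s[0:n] = board.coins
        s[3 * n:4 * n] = -1
        s[4 * n:4 * n + 2 * figures_per_player] = -1
        return cls(s, board.rows, board.cols, figures_per_player)

    @classmethod
    def from_components(cls, board: Board, figures: Iterable[Figure],
                        scores: tuple[int, int], phase: Phase, to_move: Player,
                        lava: Iterable[HexCoord] = (),
                        scored: Iterable[HexCoord] = (),
                        figures_per_player: Optional[int] = None,
                        unplaced: Iterable[int] = ()) -> "GameState":
        """Assemble an arbitrary (assumed reachable) position; used by
        fixtures and tests.

        Figure ids are global: participant `0..k-1`, AI `k..2k-1` where `k`
        is `figures_per_player` (inferred from the largest id if omitted).
        Figures left out of `figures` count as removed unless their id is
        listed in `unplaced`.
        """
        figs = list(figures)
        if figures_per_player is None:
            k = (max(f.index for f in figs) + 2) // 2 if figs else 1
        else:
            k = figures_per_player
        n = board.rows * board.cols
        s = np.zeros(_core.state_size(board.rows, board.cols, k), dtype=np.int16)
        s[0:n] = board.coins
        s[3 * n:4 * n] = -1
        s[4 * n:4 * n + 2 * k] = -2
        for gid in unplaced:
            s[4 * n + gid] = -1
        for f in figs:
            if f.alive and f.position is not None:
                idx = f.position.row * board.cols + f.position.col
                s[4 * n + f.index] = idx
                s[3 * n + idx] = f.index
        for c in lava:
            s[n + c.row * board.cols + c.col] = 1
        for c in scored:
            s[2 * n + c.row * board.cols + c.col] = 1
        b = 4 * n + 2 * k
        s[b] = scores[0]
        s[b + 1] = scores[1]
        s[b + 2] = int(phase)
        s[b + 3] = int(to_move)
        return cls(s, board.rows, board.cols, k)

    # -- internals ---------------------------------------------------------

    def _idx(self, c: HexCoord) -> int:
        if not (0 <= c.col < self.cols and 0 <= c.row < self.rows):
            raise IllegalMoveError(f"{c} is off the board", rule="bounds")
        return c.row * self.cols + c.col

    def _coord(self, idx: int) -> HexCoord:
        return HexCoord(int(idx) % self.cols, int(idx) // self.cols)

    @property
    def _n(self) -> int:
        return self.rows * self.cols

    @property
    def _b(self) -> int:
        return 4 * self._n + 2 * self.figures_per_player

    def copy_array(self) -> np.ndarray:
        """A mutable copy of the underlying state vector."""
        return self._s.copy()

    # -- inspection --------------------------------------------------------

    @property
    def phase(self) -> Phase:
        return Phase(int(self._s[self._b + 2]))

    @property
    def to_move(self) -> Player:
        return Player(int(self._s[self._b + 3]))

    @property
    def is_terminal(self) -> bool:
        return self.phase == Phase.TERMINAL

    @property
    def scores(self) -> tuple[int, int]:
        return int(self._s[self._b]), int(self._s[self._b + 1])

    @property
    def total_coins(self) -> int:
        return int(self._s[0:self._n].sum())

    @property
    def board(self) -> Board:
        return Board(self.rows, self.cols, self._s[0:self._n].copy())

    @property
    def tiles(self) -> dict[HexCoord, Tile]:
        n = self._n
        return {
            self._coord(i): Tile(int(self._s[i]), bool(self._s[n + i]),
                                 bool(self._s[2 * n + i]))
            for i in range(n)
        }

    @property
    def figures(self) -> list[Figure]:
        n, k = self._n, self.figures_per_player
        out = []
        for gid in range(2 * k):
            pos = int(self._s[4 * n + gid])
            owner = Player.PARTICIPANT if gid < k else Player.AI
            out.append(Figure(owner, gid,
                              self._coord(pos) if pos >= 0 else None,
                              pos >= 0))
        return out

    @property
    def lava_count(self) -> int:
        n = self._n
        return int(self._s[n:2 * n].sum())

    @property
    def forfeited_coins(self) -> int:
        """Coins lost to lava without ever being scored."""
        n = self._n
        lava = self._s[n:2 * n] != 0
        scored = self._s[2 * n:3 * n] != 0
        return int(self._s[0:n][lava & ~scored].sum())

    @property
    def open_unscored_coins(self) -> int:
        n = self._n
        lava = self._s[n:2 * n] != 0
        scored = self._s[2 * n:3 * n] != 0
        return int(self._s[0:n][~lava & ~scored].sum())

    def next_unplaced_figure(self, player: Player) -> Optional[int]:
        n, k = self._n, self.figures_per_player
        base = 0 if player == Player.PARTICIPANT else k
        for gid in range(base, base + k):
            if int(self._s[4 * n + gid]) == -1:
                return gid
        return None

    def __eq__(self, other) -> bool:
        return (isinstance(other, GameState)
                and self.rows == other.rows and self.cols == other.cols
                and self.figures_per_player == other.figures_per_player
                and bool(np.array_equal(self._s, other._s)))

    def __repr__(self) -> str:
        p, a = self.scores
        return (f"GameState({self.rows}x{self.cols}, phase={self.phase.name}, "
                f"to_move={self.to_move.name}, scores={p}-{a})")


# -- move conversion -------------------------------------------------------

def _move_from_row(state: GameState, row) -> Move:
    kind = MoveKind.PLACE if row[0] == 0 else MoveKind.SLIDE
    frm = state._coord(row[2]) if row[0] == 1 else None
    return Move(kind, int(row[1]), frm, state._coord(row[3]))


def _move_to_row(state: GameState, move: Move) -> tuple[int, int, int, int]:
    kind = 0 if move.kind == MoveKind.PLACE else 1
    frm = state._idx(move.frm) if move.frm is not None else -1
    return kind, move.figure, frm, state._idx(move.to)


def _gen_raw(state: GameState, player: Player):
    buf = np.zeros((_core.max_moves(state.rows, state.cols, state.figures_per_player), 4),
                   np.int16)
    n = _core.gen_moves(state._s, state.rows, state.cols, state.figures_per_player,
                        int(player), buf)
    return buf[:n]


# -- spec operations -------------------------------------------------------

def legal_placements(state: GameState) -> set[HexCoord]:
    """Open, unoccupied one-coin tiles available to the player to move."""
    if state.phase != Phase.PLACEMENT:
        raise PhaseError(f"legal_placements requires the placement phase, "
                         f"state is in {state.phase.name}")
    return {state._coord(r[3]) for r in _gen_raw(state, state.to_move)}


def legal_moves(state: GameState, player: Optional[Player] = None) -> list[Move]:
    """All straight-line slides available to `player` (default: player to move)."""
    if state.phase != Phase.MOVEMENT:
        raise PhaseError(f"legal_moves requires the movement phase, "
                         f"state is in {state.phase.name}")
    player = state.to_move if player is None else player
    return [_move_from_row(state, r) for r in _gen_raw(state, player)]


def legal_actions(state: GameState) -> list[Move]:
    """Legal moves in either non-terminal phase, as full Move objects."""
    if state.phase == Phase.TERMINAL:
        raise PhaseError("no legal actions in a terminal state")
    return [_move_from_row(state, r) for r in _gen_raw(state, state.to_move)]


def placement_move(state: GameState, to: HexCoord) -> Move:
    """The placement of the mover's next unplaced figure on `to`."""
    gid = state.next_unplaced_figure(state.to_move)
    if gid is None:
        raise IllegalMoveError(f"{state.to_move.name} has no unplaced figure",
                               rule="placement")
    return Move(MoveKind.PLACE, gid, None, to)


def _diagnose(state: GameState, move: Move) -> tuple[str, str]:
    n, k = state._n, state.figures_per_player
    s = state._s
    owner = Player.PARTICIPANT if move.figure < k else Player.AI
    if not (0 <= move.figure < 2 * k):
        return f"figure {move.figure} does not exist", "figure"
    if owner != state.to_move:
        return f"it is {state.to_move.name}'s turn, figure {move.figure} is not theirs", "turn"
    to = state._idx(move.to)
    if move.kind == MoveKind.PLACE:
        if state.phase != Phase.PLACEMENT:
            return "placement outside the placement phase", "phase"
        if s[to] != 1:
            return f"placement target {move.to} holds {int(s[to])} coins, not 1", "one-coin"
        if s[3 * n + to] != -1:
            return f"placement target {move.to} is occupied", "occupied"
        if move.figure != state.next_unplaced_figure(owner):
            return f"figure {move.figure} is not the next unplaced figure", "placement-order"
        return "unknown placement violation", "placement"
    if state.phase != Phase.MOVEMENT:
        return "slide outside the movement phase", "phase"
    pos = int(s[4 * n + move.figure])
    if pos < 0:
        return f"figure {move.figure} is not on the board", "figure"
    if move.frm is None or state._idx(move.frm) != pos:
        return f"figure {move.figure} is at {state._coord(pos)}, not {move.frm}", "origin"
    if s[n + to] != 0:
        return f"destination {move.to} is lava", "lava"
    if s[3 * n + to] != -1:
        return f"destination {move.to} is occupied", "occupied"
    return (f"no clear straight line from {move.frm} to {move.to} "
            "(path blocked or not a hex line)", "line")


def apply_move(state: GameState, move: Move) -> GameState:
    """Apply a legal move and return the successor state.

    Slides turn the origin tile to lava and score the destination's coins;
    afterwards every figure (either player) left without a legal slide is
    removed, its tile turned to lava and its coins forfeited. Placements
    never score. Raises :class:`PhaseError` on terminal states and
    :class:`IllegalMoveError` (naming the violated rule) otherwise.
    """
    if state.phase == Phase.TERMINAL:
        raise PhaseError("cannot move in a terminal state")
    row = _move_to_row(state, move)
    legal = _gen_raw(state, state.to_move)
    if not any(tuple(r) == row for r in legal):
        msg, rule = _diagnose(state, move)
        raise IllegalMoveError(msg, rule=rule)
    s = state._s.copy()
    _core.apply_move(s, state.rows, state.cols, state.figures_per_player, *row)
    return GameState(s, state.rows, state.cols, state.figures_per_player,
                     state.move_history + (move,))


def outcome(state: GameState) -> tuple[int, int, Result]:
    """Terminal scores and the result from the participant's point of view."""
    if state.phase != Phase.TERMINAL:
        raise PhaseError("outcome requires a terminal state")
    p, a = state.scores
    if p > a:
        res = Result.PLAYER_WIN
    elif p == a:
        res = Result.DRAW
    else:
        res = Result.PLAYER_LOSS
    return p, a, res


def pwm(participant_score: int, ai_score: int) -> int:
    """Player win margin: participant score minus AI score."""
    if participant_score < 0 or ai_score < 0:
        raise ConfigurationError("scores must be non-negative")
    return participant_score - ai_score


def render(state: GameState) -> str:
    """ASCII view: odd rows indented; `E#`/`O#` figures, `##` lava, else coins."""
    n, k = state._n, state.figures_per_player
    s = state._s
    lines = []
    for r in range(state.rows):
        cells = []
        for c in range(state.cols):
            i = r * state.cols + c
            gid = int(s[3 * n + i])
            if gid != -1:
                label = f"E{gid}" if gid < k else f"O{gid - k}"
            elif s[n + i]:
                label = "##"
            else:
                label = f".{int(s[i])}"
            cells.append(label)
        indent = "  " if r % 2 == 1 else ""
        lines.append(indent + " ".join(cells))
    p, a = state.scores
    lines.append(f"scores E:{p} O:{a}  phase:{state.phase.name} "
                 f"to_move:{'E' if state.to_move == Player.PARTICIPANT else 'O'}")
    return "\n".join(lines)
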