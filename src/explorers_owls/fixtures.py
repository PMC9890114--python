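"""Deterministic test fixtures: tiny boards, mid-game and terminal states.

Fixture positions are *searched for* with a seeded random walk and then
*certified* — a "forced win" is verified by exhaustive game-tree evaluation,
a "stranding" position by actually applying the move and counting removed
figures. The same seed always yields the same fixture files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .engine import (GameState, Move, Phase, apply_move, generate_board,
                     legal_actions, tutorial_board)
from .errors import ExplorersOwlsError
from .exact import exact_standard_values
from .io import canonical_json, state_to_dict

TINY_COUNTS_3X3 = {1: 7, 2: 1, 3: 1}


def _random_walk(state: GameState, rng: np.random.Generator):
    """Yield successive states of one uniformly random game."""
    while not state.is_terminal:
        acts = legal_actions(state)
        state = apply_move(state, acts[int(rng.integers(len(acts)))])
        yield state


def find_forced_win_state(seed: int, max_boards: int = 200) -> GameState:
    """A 3x3 one-figure-per-player movement position in which *exactly one*
    legal move leads to a won game for the mover (certified exhaustively)."""
    rng = np.random.default_rng(seed)
    for _ in range(max_boards):
        board = generate_board(3, 3, TINY_COUNTS_3X3, int(rng.integers(2 ** 31)),
                               figures_per_player=1)
        state = GameState.new(board, 1)
        for nxt in _random_walk(state, rng):
            if nxt.is_terminal or nxt.phase != Phase.MOVEMENT:
                continue
            values = exact_standard_values(nxt)
            if len(values) < 2:
                continue
            winning = [v for _, v in values if v >= 1.0]
            if len(winning) == 1:
                return nxt
    raise ExplorersOwlsError("no forced-win position found; widen the search")


def find_stranding_state(seed: int, max_boards: int = 200) -> tuple[GameState, Move]:
    """A position plus a legal slide whose stranding sweep removes at least
    one extra figure (engine-verified)."""
    rng = np.random.default_rng(seed)
    for _ in range(max_boards):
        board = generate_board(4, 4, {1: 12, 2: 2, 3: 2}, int(rng.integers(2 ** 31)),
                               figures_per_player=2)
        state = GameState.new(board, 2)
        for nxt in _random_walk(state, rng):
            if nxt.is_terminal or nxt.phase != Phase.MOVEMENT:
                continue
            before = sum(f.alive for f in nxt.figures)
            for move in legal_actions(nxt):
                after_state = apply_move(nxt, move)
                after = sum(f.alive for f in after_state.figures)
                # a plain slide keeps the mover alive: alive count < before
                # means the sweep removed someone
                if after < before:
                    return nxt, move
    raise ExplorersOwlsError("no stranding position found; widen the search")


def build_fixture_states(seed: int) -> dict[str, dict]:
    """All fixture payloads, keyed by name (JSON-ready)."""
    rng = np.random.default_rng(seed)
    fixtures: dict[str, dict] = {}

    forced = find_forced_win_state(seed)
    fixtures["forced_win_3x3"] = {"state": state_to_dict(forced)}

    stranded_state, stranding_move = find_stranding_state(seed + 1)
    fixtures["stranded"] = {
        "state": state_to_dict(stranded_state),
        "stranding_move": {
            "kind": stranding_move.kind.value,
            "figure": stranding_move.figure,
            "from": [stranding_move.frm.col, stranding_move.frm.row],
            "to": [stranding_move.to.col, stranding_move.to.row],
        },
    }

    tut = GameState.new(tutorial_board(seed), 1)
    fixtures["tutorial_start_4x4"] = {"state": state_to_dict(tut)}

    # a mid-game and a terminal state from one random tutorial game
    mid = None
    last = tut
    for s in _random_walk(tut, rng):
        if s.phase == Phase.MOVEMENT and mid is None:
            mid = s
        last = s
    fixtures["midgame_4x4"] = {"state": state_to_dict(mid if mid is not None else last)}
    fixtures["terminal_4x4"] = {"state": state_to_dict(last)}
    return fixtures


def write_fixtures(out_dir, seed: int) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    fixtures = build_fixture_states(seed)
    for name, payload in fixtures.items():
        p = out / f"{name}.json"
        p.write_text(canonical_json({"name": name, "seed": seed, **payload}) + "\n")
        paths.append(p)
    manifest = out / "manifest.json"
    manifest.write_text(canonical_json(
        {"seed": seed, "fixtures": sorted(fixtures)}) + "\n")
    paths.append(manifest)
    return paths
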