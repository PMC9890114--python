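"""Rules-engine unit tests: board generation, legality, transitions, scoring."""

import numpy as np
import pytest

import explorers_owls as eo
from explorers_owls.engine import (Board, Figure, GameState, HexCoord, Move,
                                   MoveKind, Phase, Player, Result)
from explorers_owls.errors import (ConfigurationError, IllegalMoveError,
                                   PhaseError)
from explorers_owls.fixtures import find_stranding_state

# ---------------------------------------------------------------------------
# independent hex-geometry oracle (axial arithmetic, separate from the engine)

AXIAL_DIRS = [(1, 0), (-1, 0), (1, -1), (0, -1), (0, 1), (-1, 1)]


def axial_to_offset(q, r):
    return q + (r - (r & 1)) // 2, r


def oracle_slides(state):
    """Brute-force slide enumeration over all 6 axial rays."""
    tiles = state.tiles
    occupied = {f.position for f in state.figures if f.alive}
    moves = set()
    for f in state.figures:
        if not f.alive or f.owner != state.to_move:
            continue
        q, r = f.position.to_axial()
        for dq, dr in AXIAL_DIRS:
            cq, cr = q, r
            while True:
                cq, cr = cq + dq, cr + dr
                col, row = axial_to_offset(cq, cr)
                if not (0 <= col < state.cols and 0 <= row < state.rows):
                    break
                coord = HexCoord(col, row)
                if tiles[coord].lava or coord in occupied:
                    break
                moves.add((f.index, f.position, coord))
    return moves


def engine_slides(state):
    return {(m.figure, m.frm, m.to) for m in eo.legal_moves(state)}


def open_board(rows, cols, coins=1):
    return Board(rows, cols, np.full(rows * cols, coins, dtype=np.int16))


# ---------------------------------------------------------------------------
# board generation

def test_standard_board_counts_and_total():
    b = eo.generate_board(7, 7, {1: 26, 2: 14, 3: 9}, seed=42)
    assert b.rows * b.cols == 49
    assert b.total_coins == 81
    values, counts = np.unique(b.coins, return_counts=True)
    assert dict(zip(values.tolist(), counts.tolist())) == {1: 26, 2: 14, 3: 9}


def test_all_ones_board():
    b = eo.generate_board(4, 4, {1: 16}, seed=7, figures_per_player=1)
    assert b.total_coins == 16
    assert len(b.tiles) == 16


def test_board_generation_deterministic():
    a = eo.generate_board(7, 7, {1: 26, 2: 14, 3: 9}, seed=42)
    b = eo.generate_board(7, 7, {1: 26, 2: 14, 3: 9}, seed=42)
    assert np.array_equal(a.coins, b.coins)
    c = eo.generate_board(7, 7, {1: 26, 2: 14, 3: 9}, seed=43)
    assert not np.array_equal(a.coins, c.coins)


@pytest.mark.parametrize("rows,cols,counts,figs", [
    (7, 7, {1: 26, 2: 14, 3: 8}, 3),       # 48 tiles for a 49-tile grid
    (7, 7, {1: 5, 2: 35, 3: 9}, 3),        # too few one-coin tiles to place 6
    (3, 3, {1: 8, 4: 1}, 1),               # coin value outside {1,2,3}
])
def test_board_generation_rejects_bad_configs(rows, cols, counts, figs):
    with pytest.raises(ConfigurationError):
        eo.generate_board(rows, cols, counts, seed=0, figures_per_player=figs)


def test_tutorial_board_defaults():
    b = eo.tutorial_board(3)
    assert (b.rows, b.cols) == (4, 4)
    assert b.total_coins == 10 + 2 * 4 + 3 * 2


# ---------------------------------------------------------------------------
# placement phase

def test_fresh_standard_board_has_26_placements(std_state):
    assert len(eo.legal_placements(std_state)) == 26


def test_placement_occupancy_excludes_tile(std_state):
    coord = sorted(eo.legal_placements(std_state))[0]
    nxt = eo.apply_move(std_state, eo.placement_move(std_state, coord))
    assert len(eo.legal_placements(nxt)) == 25
    assert coord not in eo.legal_placements(nxt)
    # placements never score, and the turn alternates
    assert nxt.scores == (0, 0)
    assert nxt.to_move == Player.AI


def test_placements_empty_without_one_coin_tiles():
    state = GameState.from_components(
        open_board(3, 3, coins=2), [], (0, 0), Phase.PLACEMENT,
        Player.PARTICIPANT, figures_per_player=1, unplaced=[0, 1])
    assert eo.legal_placements(state) == set()


def test_placement_on_multicoin_tile_rejected(std_state):
    idx = int(np.argmax(std_state.board.coins == 3))
    coord = HexCoord(idx % 7, idx // 7)
    with pytest.raises(IllegalMoveError) as err:
        eo.apply_move(std_state, eo.placement_move(std_state, coord))
    assert err.value.rule == "one-coin"


def test_legal_placements_phase_error():
    state = GameState.from_components(
        open_board(3, 3), [Figure(Player.PARTICIPANT, 0, HexCoord(0, 0), True)],
        (0, 0), Phase.MOVEMENT, Player.PARTICIPANT, figures_per_player=1)
    with pytest.raises(PhaseError):
        eo.legal_placements(state)


def test_participant_places_first_then_alternation(std_state):
    state = std_state
    expected = [Player.PARTICIPANT, Player.AI] * 3
    for who in expected:
        assert state.phase == Phase.PLACEMENT
        assert state.to_move == who
        coord = sorted(eo.legal_placements(state))[0]
        state = eo.apply_move(state, eo.placement_move(state, coord))
    # after all six placements, movement opens with the participant
    assert state.phase == Phase.MOVEMENT
    assert state.to_move == Player.PARTICIPANT


# ---------------------------------------------------------------------------
# movement phase

def test_center_figure_open_4x4_matches_axial_oracle():
    state = GameState.from_components(
        open_board(4, 4), [Figure(Player.PARTICIPANT, 0, HexCoord(1, 1), True)],
        (0, 0), Phase.MOVEMENT, Player.PARTICIPANT, figures_per_player=1)
    got = engine_slides(state)
    assert got == oracle_slides(state)
    assert len(got) == 9  # hand count: E2 W1 NE1 NW1 SE2 SW2


@pytest.mark.parametrize("seed", range(8))
def test_slides_match_axial_oracle_on_random_midgame_states(seed, random_game):
    board = eo.generate_board(5, 5, {1: 17, 2: 5, 3: 3}, seed=seed,
                              figures_per_player=2)
    for state in random_game(board, 2, seed):
        if state.phase == Phase.MOVEMENT:
            assert engine_slides(state) == oracle_slides(state)


def test_fully_lava_surrounded_figure_has_no_moves():
    center = HexCoord(1, 1)
    ring = [HexCoord(2, 1), HexCoord(0, 1), HexCoord(2, 0), HexCoord(1, 0),
            HexCoord(2, 2), HexCoord(1, 2)]  # all 6 odd-row neighbours
    state = GameState.from_components(
        open_board(4, 4), [Figure(Player.PARTICIPANT, 0, center, True)],
        (0, 0), Phase.MOVEMENT, Player.PARTICIPANT, figures_per_player=1,
        lava=ring)
    assert eo.legal_moves(state) == []


def test_own_figure_blocks_at_distance_two():
    # single row: only E/W rays exist; a friendly figure 2 tiles east caps
    # the eastward run at distance 1
    state = GameState.from_components(
        open_board(1, 5),
        [Figure(Player.PARTICIPANT, 0, HexCoord(0, 0), True),
         Figure(Player.PARTICIPANT, 1, HexCoord(2, 0), True)],
        (0, 0), Phase.MOVEMENT, Player.PARTICIPANT, figures_per_player=2)
    dest_of_fig0 = {m.to for m in eo.legal_moves(state) if m.figure == 0}
    assert dest_of_fig0 == {HexCoord(1, 0)}


def test_slide_scores_destination_and_burns_origin():
    board = Board(1, 3, np.array([1, 3, 2], dtype=np.int16))
    state = GameState.from_components(
        board, [Figure(Player.PARTICIPANT, 0, HexCoord(0, 0), True)],
        (0, 0), Phase.MOVEMENT, Player.PARTICIPANT, figures_per_player=1)
    move = [m for m in eo.legal_moves(state) if m.to == HexCoord(1, 0)][0]
    nxt = eo.apply_move(state, move)
    assert nxt.scores == (3, 0)
    assert nxt.tiles[HexCoord(0, 0)].lava


def test_sealing_slide_removes_stranded_figure_in_same_transition():
    state, move = find_stranding_state(0)
    before = sum(f.alive for f in state.figures)
    after_state = eo.apply_move(state, move)
    assert sum(f.alive for f in after_state.figures) < before
    assert after_state.lava_count > state.lava_count + 1  # origin + victim tile


def test_slide_through_occupied_tile_rejected():
    state = GameState.from_components(
        open_board(1, 5),
        [Figure(Player.PARTICIPANT, 0, HexCoord(0, 0), True),
         Figure(Player.PARTICIPANT, 1, HexCoord(2, 0), True)],
        (0, 0), Phase.MOVEMENT, Player.PARTICIPANT, figures_per_player=2)
    bad = Move(MoveKind.SLIDE, 0, HexCoord(0, 0), HexCoord(3, 0))
    with pytest.raises(IllegalMoveError):
        eo.apply_move(state, bad)


def test_move_on_terminal_state_is_phase_error(random_game, std_board):
    terminal = random_game(std_board, 3, 0)[-1]
    assert terminal.is_terminal
    with pytest.raises(PhaseError):
        eo.apply_move(terminal, Move(MoveKind.SLIDE, 0, HexCoord(0, 0),
                                     HexCoord(1, 0)))


# ---------------------------------------------------------------------------
# outcome and PWM

def test_outcome_requires_terminal(std_state):
    with pytest.raises(PhaseError):
        eo.outcome(std_state)


def test_outcome_and_pwm_semantics(random_game, std_board):
    terminal = random_game(std_board, 3, 1)[-1]
    p, a, res = eo.outcome(terminal)
    assert (p, a) == terminal.scores
    expected = (Result.PLAYER_WIN if p > a
                else Result.DRAW if p == a else Result.PLAYER_LOSS)
    assert res == expected


@pytest.mark.parametrize("p,a,expected", [
    (45, 30, 15), (30, 30, 0), (0, 81, -81), (15, 30, -15),
])
def test_pwm_is_signed_margin(p, a, expected):
    assert eo.pwm(p, a) == expected


def test_pwm_rejects_negative_scores():
    with pytest.raises(ConfigurationError):
        eo.pwm(-1, 0)
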