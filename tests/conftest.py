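import numpy as np
import pytest

import explorers_owls as eo


@pytest.fixture(scope="session")
def std_board():
    return eo.standard_board(42)


@pytest.fixture
def std_state(std_board):
    return eo.GameState.new(std_board, 3)


@pytest.fixture(scope="session")
def tiny_board_spec():
    """A 4x4, two-figure board family for fast end-to-end runs."""
    return eo.BoardSpec(rows=4, cols=4, coin_counts={1: 12, 2: 2, 3: 2},
                        figures_per_player=2)


def random_game_states(board, figures_per_player, seed):
    """All states of one uniformly random game played through the public API."""
    rng = np.random.default_rng(seed)
    state = eo.GameState.new(board, figures_per_player)
    states = [state]
    while not state.is_terminal:
        acts = eo.legal_actions(state)
        state = eo.apply_move(state, acts[int(rng.integers(len(acts)))])
        states.append(state)
    return states


@pytest.fixture(scope="session")
def random_game():
    return random_game_states
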