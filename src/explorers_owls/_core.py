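"""Compiled hot path: flat-array game state, move generation, transitions,
random playouts and the full MCTS loop.

The public modules (:mod:`engine`, :mod:`mcts`) wrap these kernels; nothing
here validates input — legality checks live in the Python layer.

State vector layout (``int16``), for a ``rows x cols`` board with ``nfig``
figures per player (``N = rows*cols``, ``F = 2*nfig``):

====================  =======================================================
``S[0:N]``            coins per tile (1..3), immutable after generation
``S[N:2N]``           lava flag per tile (0/1)
``S[2N:3N]``          "scored" flag: tile's coins already credited to a score
``S[3N:4N]``          occupancy: -1 empty, else figure id (0..F-1)
``S[4N:4N+F]``        figure position: tile index, -1 unplaced, -2 removed
``S[4N+F]``           participant score
``S[4N+F+1]``         AI score
``S[4N+F+2]``         phase: 0 placement, 1 movement, 2 terminal
``S[4N+F+3]``         player to move: 0 participant, 1 AI
====================  =======================================================

Figures ``0..nfig-1`` belong to the participant, ``nfig..F-1`` to the AI.
Tiles are indexed row-major over an "odd-r" horizontal hex layout (odd rows
shifted half a tile to the right); the six slide directions are the axial
unit vectors, expressed below as parity-dependent (dcol, drow) steps.
"""

import numpy as np
from numba import njit

# (dcol, drow) per [row parity][direction]; directions E, W, NE, NW, SE, SW
_DC = np.array([[1, -1, 0, -1, 0, -1],
                [1, -1, 1, 0, 1, 0]], dtype=np.int16)
_DR = np.array([[0, 0, -1, -1, 1, 1],
                [0, 0, -1, -1, 1, 1]], dtype=np.int16)

PHASE_PLACEMENT = 0
PHASE_MOVEMENT = 1
PHASE_TERMINAL = 2

MODE_STANDARD = 0
MODE_OSAS = 1
MODE_TRUE_POSAS = 2


def state_size(rows: int, cols: int, nfig: int) -> int:
    return 4 * rows * cols + 2 * nfig + 4


def max_moves(rows: int, cols: int, nfig: int) -> int:
    # placement: <= N one-coin tiles; movement: per figure, 6 rays of at most
    # max(rows, cols) steps each
    n = rows * cols
    return max(n, 6 * nfig * max(rows, cols)) + 1


@njit(cache=True)
def _fig_has_move(S, rows, cols, nfig, fig):
    N = rows * cols
    pos = S[4 * N + fig]
    if pos < 0:
        return False
    c = pos % cols
    r = pos // cols
    p = r & 1
    for d in range(6):
        nc = c + _DC[p, d]
        nr = r + _DR[p, d]
        if 0 <= nc < cols and 0 <= nr < rows:
            idx = nr * cols + nc
            if S[N + idx] == 0 and S[3 * N + idx] == -1:
                return True
    return False


@njit(cache=True)
def gen_moves(S, rows, cols, nfig, player, out):
    """Write legal moves for `player` into `out` (kind, fig, from, to); return count."""
    N = rows * cols
    F = 2 * nfig
    B = 4 * N + F
    phase = S[B + 2]
    n = 0
    if phase == PHASE_PLACEMENT:
        fig = -1
        base = 0 if player == 0 else nfig
        for f in range(base, base + nfig):
            if S[4 * N + f] == -1:
                fig = f
                break
        if fig == -1:
            return 0
        for idx in range(N):
            if S[idx] == 1 and S[N + idx] == 0 and S[3 * N + idx] == -1:
                out[n, 0] = 0
                out[n, 1] = fig
                out[n, 2] = -1
                out[n, 3] = idx
                n += 1
    elif phase == PHASE_MOVEMENT:
        base = 0 if player == 0 else nfig
        for f in range(base, base + nfig):
            pos = S[4 * N + f]
            if pos < 0:
                continue
            c0 = pos % cols
            r0 = pos // cols
            for d in range(6):
                c = c0
                r = r0
                while True:
                    p = r & 1
                    c2 = c + _DC[p, d]
                    r2 = r + _DR[p, d]
                    if c2 < 0 or c2 >= cols or r2 < 0 or r2 >= rows:
                        break
                    idx = r2 * cols + c2
                    if S[N + idx] != 0 or S[3 * N + idx] != -1:
                        break
                    out[n, 0] = 1
                    out[n, 1] = f
                    out[n, 2] = pos
                    out[n, 3] = idx
                    n += 1
                    c = c2
                    r = r2
    return n


@njit(cache=True)
def _strand_sweep(S, rows, cols, nfig):
    # Remove every figure with no legal slide; its tile turns to lava, which
    # can strand further figures, so iterate to a fixpoint. Row-major scan.
    N = rows * cols
    changed = True
    while changed:
        changed = False
        for idx in range(N):
            f = S[3 * N + idx]
            if f != -1:
                if not _fig_has_move(S, rows, cols, nfig, f):
                    S[3 * N + idx] = -1
                    S[4 * N + f] = -2
                    S[N + idx] = 1
                    changed = True


@njit(cache=True)
def apply_move(S, rows, cols, nfig, kind, fig, frm, to):
    """Apply a legal move in place. Caller guarantees legality."""
    N = rows * cols
    F = 2 * nfig
    B = 4 * N + F
    if kind == 0:
        S[3 * N + to] = fig
        S[4 * N + fig] = to
        all_placed = True
        for f in range(F):
            if S[4 * N + f] == -1:
                all_placed = False
                break
        if not all_placed:
            S[B + 3] = 1 - S[B + 3]
            return
        # placement done: movement phase opens with the participant to move
        S[B + 2] = PHASE_MOVEMENT
        _strand_sweep(S, rows, cols, nfig)
        desired = 0
    else:
        side = 0 if fig < nfig else 1
        S[N + frm] = 1
        S[3 * N + frm] = -1
        S[3 * N + to] = fig
        S[4 * N + fig] = to
        S[B + side] += S[to]
        S[2 * N + to] = 1
        _strand_sweep(S, rows, cols, nfig)
        desired = 1 - side
    alive0 = False
    alive1 = False
    for f in range(nfig):
        if S[4 * N + f] >= 0:
            alive0 = True
            break
    for f in range(nfig, F):
        if S[4 * N + f] >= 0:
            alive1 = True
            break
    if not alive0 and not alive1:
        S[B + 2] = PHASE_TERMINAL
        return
    if desired == 0:
        S[B + 3] = 0 if alive0 else 1
    else:
        S[B + 3] = 1 if alive1 else 0


@njit(cache=True)
def playout(S, rows, cols, nfig, buf):
    """Uniform-random playout to a terminal state, in place.

    Uses numpy's (numba-internal) global RNG; seed it before calling.
    """
    N = rows * cols
    B = 4 * N + 2 * nfig
    while S[B + 2] != PHASE_TERMINAL:
        n = gen_moves(S, rows, cols, nfig, S[B + 3], buf)
        if n == 0:
            # unreachable for validated configurations (the stranding sweep
            # guarantees every alive figure can slide; placement guarantees
            # enough one-coin tiles); guard against infinite loops anyway
            S[B + 2] = PHASE_TERMINAL
            break
        j = np.random.randint(0, n)
        apply_move(S, rows, cols, nfig, buf[j, 0], buf[j, 1], buf[j, 2], buf[j, 3])


@njit(cache=True)
def terminal_rewards(S, rows, cols, nfig, mode, target, mshift, span, draw_reward):
    """Per-player terminal rewards (participant, AI), each in [0, 1].

    The participant side always uses the standard win/draw/loss reward from
    its own perspective (the AI's opponent model); the AI side uses the
    configured reward family.
    """
    B = 4 * rows * cols + 2 * nfig
    pwm = S[B] - S[B + 1]
    if pwm > 0:
        rp = 1.0
    elif pwm == 0:
        rp = 0.5
    else:
        rp = 0.0
    if mode == MODE_STANDARD:
        if pwm < 0:
            ra = 1.0
        elif pwm == 0:
            ra = draw_reward
        else:
            ra = 0.0
    else:
        if mode == MODE_OSAS:
            lo = target - mshift
            hi = target
        else:
            lo = target
            hi = target + mshift
        if lo <= pwm <= hi:
            ra = 1.0
        else:
            d = lo - pwm if pwm < lo else pwm - hi
            ra = 1.0 - d / span
            if ra < 0.0:
                ra = 0.0
    return rp, ra


@njit(cache=True)
def mcts_search(S0, rows, cols, nfig, iters, c, seed,
                mode, target, mshift, span, draw_reward,
                final_sel, maxm):
    """Full MCTS: selection (UCB1) / expansion / random simulation /
    backpropagation, repeated `iters` times from `S0`.

    final_sel: 0 = max mean reward for the searching player, 1 = max visits;
    ties broken by higher visit count, then uniformly at random.

    Returns (best_move[4], child_moves[k,4], child_visits[k], child_mean[k,2],
    root_visits).
    """
    np.random.seed(seed)
    N = rows * cols
    B = 4 * N + 2 * nfig
    cap = iters + 2
    parent = np.full(cap, -1, np.int64)
    mv = np.zeros((cap, 4), np.int16)
    visits = np.zeros(cap, np.int64)
    rew = np.zeros((cap, 2), np.float64)
    tomove = np.zeros(cap, np.uint8)
    term = np.zeros(cap, np.uint8)
    first_child = np.full(cap, -1, np.int64)
    next_sib = np.full(cap, -1, np.int64)
    ustart = np.zeros(cap, np.int64)
    ucount = np.zeros(cap, np.int64)
    ubuf = np.zeros((cap * maxm, 4), np.int16)
    buf = np.zeros((maxm, 4), np.int16)
    S = np.empty_like(S0)

    tomove[0] = S0[B + 3]
    term[0] = 1 if S0[B + 2] == PHASE_TERMINAL else 0
    n0 = gen_moves(S0, rows, cols, nfig, S0[B + 3], buf)
    ustart[0] = 0
    ucount[0] = n0
    for q in range(n0):
        for z in range(4):
            ubuf[q, z] = buf[q, z]
    uoff = n0
    nnodes = 1

    for _ in range(iters):
        S[:] = S0
        node = 0
        # selection: descend by urgency to a node with untried moves or terminal
        while term[node] == 0 and ucount[node] == 0 and first_child[node] != -1:
            pl = tomove[node]
            lp = np.log(visits[node])
            best = -1
            bestu = -1e300
            ch = first_child[node]
            while ch != -1:
                u = rew[ch, pl] / visits[ch] + c * np.sqrt(lp / visits[ch])
                if u > bestu:
                    bestu = u
                    best = ch
                ch = next_sib[ch]
            node = best
            apply_move(S, rows, cols, nfig,
                       mv[node, 0], mv[node, 1], mv[node, 2], mv[node, 3])
        # expansion: one random untried move
        if term[node] == 0 and ucount[node] > 0:
            j = np.random.randint(0, ucount[node])
            row = ustart[node] + j
            last = ustart[node] + ucount[node] - 1
            k0 = ubuf[row, 0]
            f0 = ubuf[row, 1]
            fr0 = ubuf[row, 2]
            t0 = ubuf[row, 3]
            for z in range(4):
                ubuf[row, z] = ubuf[last, z]
            ucount[node] -= 1
            apply_move(S, rows, cols, nfig, k0, f0, fr0, t0)
            new = nnodes
            nnodes += 1
            parent[new] = node
            mv[new, 0] = k0
            mv[new, 1] = f0
            mv[new, 2] = fr0
            mv[new, 3] = t0
            tomove[new] = S[B + 3]
            term[new] = 1 if S[B + 2] == PHASE_TERMINAL else 0
            if term[new] == 0:
                nn = gen_moves(S, rows, cols, nfig, S[B + 3], buf)
                ustart[new] = uoff
                ucount[new] = nn
                for q in range(nn):
                    for z in range(4):
                        ubuf[uoff + q, z] = buf[q, z]
                uoff += nn
            next_sib[new] = first_child[node]
            first_child[node] = new
            node = new
        # simulation
        if S[B + 2] != PHASE_TERMINAL:
            playout(S, rows, cols, nfig, buf)
        rp, ra = terminal_rewards(S, rows, cols, nfig,
                                  mode, target, mshift, span, draw_reward)
        # backpropagation
        nd = node
        while nd != -1:
            visits[nd] += 1
            rew[nd, 0] += rp
            rew[nd, 1] += ra
            nd = parent[nd]

    # final selection among root children
    rootp = tomove[0]
    best = -1
    bestscore = -1e300
    bestv = -1
    nbest = 0
    ch = first_child[0]
    while ch != -1:
        if final_sel == 0:
            sc = rew[ch, rootp] / visits[ch]
        else:
            sc = float(visits[ch])
        if best == -1 or sc > bestscore + 1e-12:
            best = ch
            bestscore = sc
            bestv = visits[ch]
            nbest = 1
        elif sc > bestscore - 1e-12:
            if visits[ch] > bestv:
                best = ch
                bestv = visits[ch]
                nbest = 1
            elif visits[ch] == bestv:
                nbest += 1
                if np.random.randint(0, nbest) == 0:
                    best = ch
        ch = next_sib[ch]

    k = 0
    ch = first_child[0]
    while ch != -1:
        k += 1
        ch = next_sib[ch]
    child_moves = np.zeros((k, 4), np.int16)
    child_visits = np.zeros(k, np.int64)
    child_mean = np.zeros((k, 2), np.float64)
    i = 0
    ch = first_child[0]
    while ch != -1:
        for z in range(4):
            child_moves[i, z] = mv[ch, z]
        child_visits[i] = visits[ch]
        child_mean[i, 0] = rew[ch, 0] / visits[ch]
        child_mean[i, 1] = rew[ch, 1] / visits[ch]
        i += 1
        ch = next_sib[ch]
    best_move = np.zeros(4, np.int16)
    for z in range(4):
        best_move[z] = mv[best, z]
    return best_move, child_moves, child_visits, child_mean, visits[0]


@njit(cache=True)
def seeded_playout(S, rows, cols, nfig, buf, seed):
    """Seed the kernel RNG, then run one random playout in place."""
    np.random.seed(seed)
    playout(S, rows, cols, nfig, buf)
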