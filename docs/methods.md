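# Methods

## Game model

*Explorers vs Owls* is a deterministic, perfect-information, zero-sum,
turn-based game. The only randomness is the initial board: a seeded
generator shuffles a fixed multiset of tile values over the grid.

**Board.** Hex tiles in an "odd-r" horizontal offset layout (odd rows
shifted half a tile right), mapped to axial coordinates; the six slide
directions are the six axial unit vectors. The standard 7×7 board uses the
coin mix {1-coin: 26, 2-coin: 14, 3-coin: 9} — 49 tiles, 81 coins — so the
final margin always lies in [−81, 81] and the margin scale spans 162
points. The mix itself is a package design choice constrained by the 81
total, the 1–3 per-tile range, and the need for at least six one-coin
placement tiles; the tutorial 4×4 board uses {10, 4, 2}.

**Rules as implemented, including choices the rules text leaves open:**

- Placement: players alternate single placements on open, unoccupied
  one-coin tiles, participant first, until each side has placed all
  figures (three in the standard game, one in the tutorial). Placements do
  **not** score; the placed tile's coin is forfeited if the figure later
  slides off it. The alternative reading (collecting the single coin on
  placement) would shift both scores equally and keeps |PWM| ≤ 81 either
  way; not scoring is the literal reading of "score increases by the
  coins on the tile they move to".
- Slides: any distance along one of the six rays, over open, unoccupied
  tiles only, stopping strictly before the first blocker. The origin turns
  to lava; the destination's coins are credited to the mover once (a tile
  can only ever be scored once, because a figure leaving it burns it).
- Stranding: after every slide — and once on entry to the movement phase —
  every figure (both players) with no legal slide is removed, its tile
  turned to lava and its coins forfeited, iterating in row-major scan
  order to a fixpoint since each removal creates lava that can strand
  further figures. Forfeiting (rather than scoring) a stranded figure's
  tile is the conservative reading; it is also what makes the coin
  conservation identity exact: participant score + AI score + unscored
  open coins + unscored lava coins = 81.
- Turn order: participant moves first in each phase; a player with no
  remaining figures is skipped; the game is terminal when no figures
  remain. Because the stranding sweep removes immobile figures, "has a
  figure but no move" cannot persist, and every slide adds at least one
  lava tile, so a game ends within (tiles + placements) actions.

## Search

MCTS with the four canonical phases. The urgency function is UCB1,
`mean + c·√(ln N_parent / n_child)`, with default `c = √2`; unvisited
children rank +∞. Playouts are uniformly random with no heuristics.
Terminal evaluation produces a **per-player reward pair**: the AI side uses
the configured reward family; the participant side always uses the
standard win/draw/loss reward from its own perspective. At every tree node
the urgency (and the final root selection) uses the component of the player
to move at that node's parent — the AI plans against a player who is trying
to win, not one who cooperates with its target. Final move selection
maximises mean reward for the searching player (max-visits available as an
alternative); ties break to the higher visit count, then a seeded random
pick (tolerance 1e-12 on the mean). The default per-move budget is 7500
iterations; budgets count playouts, never wall-clock time.

Two engines implement the identical algorithm: an explicit Python node
tree (inspectable, supports arbitrary reward callables) and a
numba-compiled kernel over flat `int16` state arrays used by default. They
consume different random streams, so tests assert agreement on certified
best moves and invariants per engine, not playout-by-playout identity.

## Reward functions

- `standard`: AI win → 1, loss → 0, draw → `draw_reward` (default 0.5).
  It is a separate function, never a limit case of the graded family
  (a zero span is rejected as a configuration error).
- graded (`osas` / `true_posas`): reward 1 on an integer-margin plateau of
  width `max_move_score + 1`, linear decay `1 − d/span` outside it, floored
  at 0 (keeping UCB1 means in [0, 1]). `true_posas` places the plateau at
  `[target, target + max_move_score]`, compensating the participant's
  first-mover advantage by aiming slightly above the nominal target;
  `osas` is the unshifted variant with the apex (upper plateau edge)
  exactly at the target. Defaults: `max_move_score = 3` (the per-tile coin
  maximum), `span = 162` (the full margin scale). The decay width is a
  configuration point; the full span is the default because it gives a
  nonzero gradient everywhere in range, which matters early in the search
  when playouts are far from the target.

Conditions: easy +15, balanced 0, hard −15; tutorial AI always targets 0.

## Scripted participants

Human players are replaced by scripted policies forming a skill ladder:
uniform-random; coin-greedy (argmax destination coins, uniform ties and
placements); standard-reward MCTS with a configurable budget. Measured win
rates against a random opponent over 200 standard-board games rise
monotonically (~0.53 / 0.86 / 0.97 / 1.00 for random, greedy, MCTS-100,
MCTS-1000). Participant heterogeneity is modelled by sampling specs from a
pool (log-spaced budgets by default). What these policies do **not**
emulate: human learning across games, fatigue, move-time variation, or
human-typical error patterns — so passing target-tracking tests shows the
controller handles a *static* range of skills, not that it tracks a
drifting human learner (though per-match adaptation is exactly what the
between-game improvement statistic probes).

## Experiment harness

`run_study` assigns sessions to conditions round-robin; each session plays
`games` full matches (default 2, standard board, three figures). One master
`SeedSequence` fans out to per-session, per-match (board, participant RNG,
search base) and per-move search seeds — every match record logs its seeds
and can be replayed in isolation. Summaries report per-condition mean/SD
(sample SD, absent for n = 1), median, win/draw/loss percentages and
PWM-improvement statistics; outcome rates and PWM statistics use the final
match of each session by default, with a documented pooled mode. Human
self-report measures (enjoyment, agency, play-again) have no simulated
counterpart and are simply absent.

Between-condition differences use the Kruskal–Wallis test (SciPy,
tie-corrected; the all-identical degenerate case is defined as H = 0) with
the effect size ε² = H·(n+1)/(n²−1), and Dunn's pairwise rank tests with
Holm correction (implemented in-package: z = ΔR̄ / √((N(N+1)/12 − T)(1/nᵢ +
1/nⱼ)) with tie term T = Σ(t³−t)/(12(N−1))).

## Problem sizes and numerical choices in the shipped tests

- Target-tracking study: 30 sessions × 2 games per condition, True POSAS
  at 2000 iterations vs the greedy participant (median final PWM within ±6
  of target, strict ordering, KW p < 0.001, median improvement within ±3).
- Exhaustive-search agreement: 3×3 boards, one figure per player, 20 000
  iterations, chosen move within 0.05 of the exact game value computed by
  memoised backward induction.
- Engine invariants: 10 000 random playouts with per-step checks of coin
  conservation, monotone lava, score monotonicity, the termination bound
  and the ±81 margin bound; legality closure via full-API games plus
  rejected perturbed moves.
- Skill ladder: 200 games per rung.

Fixture positions ("forced win", "stranding") are found by seeded random
walks and then *certified* — by exhaustive evaluation or by applying the
move — so the same seed always reproduces byte-identical fixture files.

## Known limitations

- The graded reward targets only the final score margin; positional
  targets are out of scope.
- No tree reuse between moves, transpositions, parallelism or playout
  heuristics; strength comes from the iteration budget alone.
- The greedy/MCTS participant pool brackets a plausible skill range but
  cannot validate behaviour against skills outside it (e.g. near-perfect
  play, where the zero-sum structure caps how far the controller can miss
  or hit a target).
- With non-default `draw_reward ≠ 0.5` the two-player reward pair is not
  exactly zero-sum; the exhaustive oracle only supports the symmetric
  case.
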