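# explorers-owls

A difficulty-controlled game test suite for computational behavioural
research: a deterministic two-player hex-grid game (*Explorers vs Owls*), an
MCTS opponent whose **outcome-sensitive reward** steers the final score
margin toward an arbitrary target, scripted stand-in players of graded
skill, and an agent-vs-agent experiment harness that validates the
difficulty manipulation.

It is aimed at researchers who need an *objective, individual-level*
manipulation of difficulty–skill ratio: instead of fixing an opponent
strength per cohort, the AI adapts within each match so that the **player
win margin** (PWM = player score − AI score) lands near a chosen target —
positive for an easy game, 0 for a draw, negative for a hard game.

## The game

Played on a 7×7 grid of hexagonal tiles, each holding 1–3 coins (81 coins
in total, so PWM ∈ [−81, 81]). Players alternately place three figures on
one-coin tiles (player first), then take turns sliding a figure any
distance along a straight hex line not blocked by lava, figures, or the
board edge. Sliding turns the origin tile to lava forever and scores the
destination's coins; a figure that can no longer slide is removed and its
tile's coins are forfeited. When all figures are gone, the higher coin
total wins. A 4×4 one-figure tutorial variant is included.

## The algorithm

The AI is Monte Carlo Tree Search (selection by the UCB1 urgency rule
`r̄ + c·√(ln N / n)`, one-node expansion, uniform-random playouts,
backpropagation of a per-player reward pair). Standard play-to-win MCTS
scores a terminal state 1/0.5/0 for an AI win/draw/loss. The
outcome-sensitive variant (OSAS) instead grades terminal states by how
close the final margin *m* is to a target *t*:

```
reward(m) = 1                        if m ∈ [t, t + 3]
            max(0, 1 − d/162)        otherwise, d = distance to the plateau
```

a "flattened cone" whose plateau is shifted up by 3 points — the maximum a
single move can score — compensating the first-mover advantage of the human
player (the **True POSAS** variant). The AI's opponent model assumes the
player plays to win. Study conditions: easy *t* = +15, balanced *t* = 0,
hard *t* = −15; the tutorial AI always aims for a draw.

The engine and the full search loop are numba-compiled, so a
2000-iteration move decision takes ~50 ms and full simulated studies run in
minutes on one CPU.

## Worked example

Simulate a scaled-down validation study — 10 sessions of 2 games per
condition, True POSAS at 2000 iterations against a coin-greedy scripted
player:

```python
from explorers_owls.experiment import run_study, summarize, study_report
from explorers_owls.mcts import SearchConfig
from explorers_owls.opponents import OpponentSpec

study = run_study(10, [OpponentSpec("greedy")], seed=1, games=2,
                  search_config=SearchConfig(iterations=2000))
for s in summarize(study):
    print(f"{s.condition:9s} target {s.target_pwm:+3d}  median PWM {s.pwm_median:+5.1f}  "
          f"win% {s.win_pct:5.1f}  improvement median {s.pwm_improvement_median:+4.1f}")
kw = study_report(study)["kruskal_wallis"]
print(f"Kruskal-Wallis H={kw['H']:.1f}, df={kw['df']}, p={kw['p']:.2e}, "
      f"eps2={kw['epsilon_sq']:.3f}")
```

prints

```
easy      target +15  median PWM +18.0  win% 100.0  improvement median -0.5
balanced  target  +0  median PWM  +1.5  win%  90.0  improvement median -1.0
hard      target -15  median PWM -12.5  win%   0.0  improvement median +1.0
Kruskal-Wallis H=26.0, df=2, p=2.32e-06, eps2=0.895
```

Per-condition median margins land close to their targets and in strict
order, the conditions separate decisively (rank test p ≪ 0.001 with a very
large ε² effect size), and the near-zero "PWM improvement" medians (last
minus first game per session) show the AI re-adapting between games.

## Command line

```
explorers-owls simulate --config study.yaml    # full study -> JSONL + CSV + KW report
explorers-owls play --condition hard --seed 3  # interactive terminal match
explorers-owls report --in matches.jsonl --out summary.csv
explorers-owls fixtures --out fixtures/        # deterministic test positions
```

Every run is reproducible from its config file alone: one master seed fans
out to per-session, per-match and per-search sub-seeds, all logged in the
match records.

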