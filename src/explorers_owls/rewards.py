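"""Terminal reward functions mapping game outcomes to [0, 1].

Two families:

* **standard** — the conventional play-to-win reward: 1 for an AI win, 0 for
  an AI loss, a configurable value (default 0.5) for a draw. An MCTS opponent
  using it plays as strongly as its budget allows.
* **graded outcome-sensitive (OSAS / True POSAS)** — a "flattened cone" over
  the final player win margin (PWM = participant score − AI score). Reward
  is 1 on a plateau of integer margins near the target and decays linearly
  with distance from the plateau, normalised by the full PWM span (162 for
  the standard board, i.e. margins in [−81, 81]), floored at 0. An MCTS
  opponent using it steers the *final margin* toward the target instead of
  maximising its own score.

  In plain OSAS mode the plateau's upper edge (apex) sits exactly at the
  target. The True POSAS variant compensates the first-mover advantage of
  the participant (who moves first) by shifting the plateau *up* by the
  maximum score obtainable in a single move (3 coins): the plateau becomes
  ``[target, target + 3]``, so the AI aims slightly above the nominal target.

Study conditions: easy targets PWM +15, balanced 0, hard −15; the tutorial
AI always aims for a draw.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

from . import _core
from .engine import GameState, Result, outcome
from .errors import ConfigurationError, ExplorersOwlsError

#: Full width of the standard board's PWM range, 162 points (−81..81).
DEFAULT_SPAN = 162
#: Maximum coins obtainable in one move: the 3-coin tile maximum.
MAX_MOVE_SCORE = 3

_MODES = ("standard", "osas", "true_posas")

CONDITION_TARGETS = {"easy": 15, "balanced": 0, "hard": -15, "tutorial": 0}


class RewardDomainError(ExplorersOwlsError, ValueError):
    """A PWM outside the configured span was passed to a graded reward."""


@dataclass(frozen=True)
class RewardSpec:
    """Reward-family configuration.

    mode: "standard", "osas" or "true_posas".
    target_pwm: targeted final margin (graded modes only).
    max_move_score: plateau width in points (default 3, the per-tile maximum).
    span: normalisation width of the linear decay (default 162, the full
        standard-board PWM range).
    draw_reward: standard-mode draw value (default 0.5).
    """

    mode: str = "true_posas"
    target_pwm: int = 0
    max_move_score: int = MAX_MOVE_SCORE
    span: int = DEFAULT_SPAN
    draw_reward: float = 0.5

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ConfigurationError(f"unknown reward mode {self.mode!r}; "
                                     f"expected one of {_MODES}")
        if self.span <= 0:
            raise ConfigurationError("span must be positive")
        if abs(self.target_pwm) > self.span / 2:
            raise ConfigurationError(
                f"target_pwm {self.target_pwm} outside ±span/2 = ±{self.span / 2:g}")
        if not (0.0 <= self.draw_reward <= 1.0):
            raise ConfigurationError("draw_reward must lie in [0, 1]")
        if self.max_move_score < 0:
            raise ConfigurationError("max_move_score must be non-negative")

    @property
    def mode_code(self) -> int:
        return {"standard": _core.MODE_STANDARD, "osas": _core.MODE_OSAS,
                "true_posas": _core.MODE_TRUE_POSAS}[self.mode]

    @property
    def plateau(self) -> tuple[int, int]:
        """Inclusive [lo, hi] range of maximal-reward integer margins."""
        if self.mode == "standard":
            raise ConfigurationError("the standard reward has no plateau")
        if self.mode == "osas":
            return self.target_pwm - self.max_move_score, self.target_pwm
        return self.target_pwm, self.target_pwm + self.max_move_score

    def to_dict(self) -> dict:
        return {"mode": self.mode, "target_pwm": self.target_pwm,
                "max_move_score": self.max_move_score, "span": self.span,
                "draw_reward": self.draw_reward}

    @classmethod
    def from_dict(cls, d: dict) -> "RewardSpec":
        return cls(**d)


def reward_standard(result: Result, spec: RewardSpec) -> float:
    """1 for an AI win, 0 for an AI loss, `spec.draw_reward` for a draw."""
    if result == Result.PLAYER_LOSS:
        return 1.0
    if result == Result.DRAW:
        return spec.draw_reward
    return 0.0


def reward_true_posas(final_pwm: int, spec: RewardSpec) -> float:
    """Graded flattened-cone reward of a final margin (osas / true_posas).

    1 on the plateau; elsewhere ``max(0, 1 − distance/span)``.
    """
    if spec.mode == "standard":
        raise ConfigurationError("graded reward requested for a standard-mode spec")
    if abs(final_pwm) > spec.span / 2:
        raise RewardDomainError(
            f"final PWM {final_pwm} outside ±span/2 = ±{spec.span / 2:g}")
    lo, hi = spec.plateau
    if lo <= final_pwm <= hi:
        return 1.0
    d = lo - final_pwm if final_pwm < lo else final_pwm - hi
    return max(0.0, 1.0 - d / spec.span)


def reward_ai(state: GameState, spec: RewardSpec) -> float:
    """The AI-side reward of a terminal state under `spec`."""
    p, a, res = outcome(state)
    if spec.mode == "standard":
        return reward_standard(res, spec)
    return reward_true_posas(p - a, spec)


def terminal_reward_pair(spec: RewardSpec) -> Callable[[GameState], tuple[float, float]]:
    """Per-player terminal reward function (participant, AI) for the search.

    The participant side is the opponent model: the AI never assumes the
    human cooperates with its outcome target, so the participant is scored
    with the standard win/draw/loss reward from their own perspective.
    """
    def fn(state: GameState) -> tuple[float, float]:
        p, a, res = outcome(state)
        rp = 1.0 if res == Result.PLAYER_WIN else (0.5 if res == Result.DRAW else 0.0)
        return rp, reward_ai(state, spec)
    return fn


def condition_spec(name: str) -> RewardSpec:
    """True POSAS spec for a study condition: easy +15, balanced 0, hard −15.

    The "tutorial" condition also aims for a draw (target 0) regardless of
    the assigned condition.
    """
    if name not in CONDITION_TARGETS:
        raise ConfigurationError(
            f"unknown condition {name!r}; expected one of {sorted(CONDITION_TARGETS)}")
    return RewardSpec(mode="true_posas", target_pwm=CONDITION_TARGETS[name])


def standard_spec(draw_reward: float = 0.5) -> RewardSpec:
    return RewardSpec(mode="standard", target_pwm=0, draw_reward=draw_reward)


def with_target(spec: RewardSpec, target_pwm: int) -> RewardSpec:
    return replace(spec, target_pwm=target_pwm)
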