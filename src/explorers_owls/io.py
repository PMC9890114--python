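"""Plain-text serialization: game states (JSON), match logs (JSON lines),
condition summaries (CSV) and study configuration (YAML/JSON).

Round-trip guarantee: ``canonical_json(state_to_dict(s))`` is byte-identical
after a parse/serialize cycle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import _core
from .engine import GameState, Phase, Player
from .errors import ConfigurationError
from .experiment import BoardSpec, ConditionSummary, MatchRecord
from .mcts import SearchConfig
from .opponents import OpponentSpec
from .rewards import RewardSpec, condition_spec

PathLike = Union[str, Path]


def canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


# -- game state -------------------------------------------------------------

def state_to_dict(state: GameState) -> dict:
    n = state.rows * state.cols
    s = state._s
    tiles = [{"col": i % state.cols, "row": i // state.cols,
              "coins": int(s[i]), "lava": bool(s[n + i]),
              "scored": bool(s[2 * n + i])}
             for i in range(n)]
    figures = []
    k = state.figures_per_player
    for gid in range(2 * k):
        pos = int(s[4 * n + gid])
        figures.append({
            "id": gid,
            "owner": "participant" if gid < k else "ai",
            "position": None if pos < 0 else [pos % state.cols, pos // state.cols],
            "status": {-1: "unplaced", -2: "removed"}.get(pos, "alive"),
        })
    return {
        "rows": state.rows, "cols": state.cols, "figures_per_player": k,
        "tiles": tiles, "figures": figures,
        "scores": list(state.scores),
        "phase": state.phase.name.lower(),
        "to_move": state.to_move.name.lower(),
    }


def state_from_dict(d: dict) -> GameState:
    rows, cols, k = d["rows"], d["cols"], d["figures_per_player"]
    n = rows * cols
    s = np.zeros(_core.state_size(rows, cols, k), dtype=np.int16)
    s[3 * n:4 * n] = -1
    for t in d["tiles"]:
        i = t["row"] * cols + t["col"]
        s[i] = t["coins"]
        s[n + i] = int(bool(t["lava"]))
        s[2 * n + i] = int(bool(t["scored"]))
    for f in d["figures"]:
        gid = f["id"]
        if f["status"] == "alive":
            i = f["position"][1] * cols + f["position"][0]
            s[4 * n + gid] = i
            s[3 * n + i] = gid
        else:
            s[4 * n + gid] = -1 if f["status"] == "unplaced" else -2
    b = 4 * n + 2 * k
    s[b] = d["scores"][0]
    s[b + 1] = d["scores"][1]
    s[b + 2] = int(Phase[d["phase"].upper()])
    s[b + 3] = int(Player[d["to_move"].upper()])
    return GameState(s, rows, cols, k)


def save_state(state: GameState, path: PathLike) -> None:
    Path(path).write_text(canonical_json(state_to_dict(state)) + "\n")


def load_state(path: PathLike) -> GameState:
    return state_from_dict(json.loads(Path(path).read_text()))


# -- match logs -------------------------------------------------------------

def write_matches_jsonl(records: list[MatchRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(canonical_json(r.to_dict()) + "\n")


def read_matches_jsonl(path: PathLike) -> list[MatchRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(MatchRecord.from_dict(json.loads(line)))
    return out


# -- summaries --------------------------------------------------------------

_SUMMARY_COLUMNS = {
    "condition": "condition",
    "n": "N",
    "target_pwm": "target PWM",
    "pwm_mean": "actual PWM mean",
    "pwm_sd": "actual PWM sd",
    "pwm_median": "actual PWM median",
    "win_pct": "player wins %",
    "draw_pct": "player draws %",
    "loss_pct": "player loses %",
    "pwm_improvement_mean": "PWM improvement mean",
    "pwm_improvement_median": "PWM improvement median",
}


def summaries_to_dataframe(summaries: list[ConditionSummary]) -> pd.DataFrame:
    df = pd.DataFrame([s.to_dict() for s in summaries])
    return df.rename(columns=_SUMMARY_COLUMNS)


def write_summary_csv(summaries: list[ConditionSummary], path: PathLike) -> None:
    summaries_to_dataframe(summaries).to_csv(path, index=False)


# -- study configuration ----------------------------------------------------

@dataclass
class RunConfig:
    """Complete, serializable configuration of a simulated study.

    A run is reproducible from this file alone: one master seed fans out to
    per-session, per-match and per-search sub-seeds.
    """

    board: BoardSpec = field(default_factory=BoardSpec)
    search: SearchConfig = field(default_factory=SearchConfig)
    conditions: tuple = ("easy", "balanced", "hard")
    opponent_pool: tuple = (OpponentSpec("greedy"),)
    n_per_condition: int = 30
    games_per_session: int = 2
    seed: int = 0
    out_dir: str = "study_out"

    def reward_specs(self) -> dict[str, RewardSpec]:
        return {c: condition_spec(c) for c in self.conditions}

    def to_dict(self) -> dict:
        return {
            "board": self.board.to_dict(),
            "search": self.search.to_dict(),
            "conditions": list(self.conditions),
            "opponent_pool": [o.to_dict() for o in self.opponent_pool],
            "n_per_condition": self.n_per_condition,
            "games_per_session": self.games_per_session,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"board", "search", "conditions", "opponent_pool",
                 "n_per_condition", "games_per_session", "seed", "out_dir"}
        for key in d:
            if key not in known:
                raise ConfigurationError(f"unknown config key {key!r}")
        kwargs: dict = {}
        try:
            if "board" in d:
                kwargs["board"] = BoardSpec.from_dict(d["board"])
            if "search" in d:
                kwargs["search"] = SearchConfig.from_dict(d["search"])
            if "opponent_pool" in d:
                kwargs["opponent_pool"] = tuple(
                    OpponentSpec.from_dict(o) for o in d["opponent_pool"])
        except TypeError as err:
            raise ConfigurationError(f"invalid config section: {err}") from err
        if "conditions" in d:
            kwargs["conditions"] = tuple(d["conditions"])
        for key in ("n_per_condition", "games_per_session", "seed", "out_dir"):
            if key in d:
                kwargs[key] = d[key]
        cfg = cls(**kwargs)
        if cfg.n_per_condition < 1:
            raise ConfigurationError("n_per_condition must be >= 1")
        if cfg.games_per_session < 1:
            raise ConfigurationError("games_per_session must be >= 1")
        return cfg

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        if "board" not in d:
            raise ConfigurationError("config is missing the 'board' section")
        return cls.from_dict(d)

    def to_yaml(self, path: PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
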