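"""Agent-vs-agent validation study.

Rebuilds the difficulty-manipulation check with scripted participants: per
condition (easy / balanced / hard, i.e. target PWM +15 / 0 / −15) each
simulated participant plays a session of full matches against the True POSAS
AI, we record per-match PWM (participant score − AI score) and per-session
PWM improvement (last match − first match), aggregate Table-style condition
summaries, and test between-condition PWM differences with a Kruskal–Wallis
test (ε² effect size) plus Dunn–Holm pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sstats

from . import opponents as opp
from .engine import (Board, GameState, Player, Result, apply_move,
                     generate_board, outcome, STANDARD_COIN_COUNTS,
                     STANDARD_FIGURES)
from .errors import AggregationError, ConfigurationError, ExplorersOwlsError
from .mcts import SearchConfig, search
from .opponents import OpponentSpec
from .rewards import CONDITION_TARGETS, RewardSpec, condition_spec

CONDITIONS = ("easy", "balanced", "hard")


@dataclass(frozen=True)
class BoardSpec:
    """Board family used for every match of a study."""

    rows: int = 7
    cols: int = 7
    coin_counts: dict = field(default_factory=lambda: dict(STANDARD_COIN_COUNTS))
    figures_per_player: int = STANDARD_FIGURES

    def make(self, seed: int) -> Board:
        return generate_board(self.rows, self.cols, self.coin_counts, seed,
                              self.figures_per_player)

    def to_dict(self) -> dict:
        return {"rows": self.rows, "cols": self.cols,
                "coin_counts": {str(k): v for k, v in self.coin_counts.items()},
                "figures_per_player": self.figures_per_player}

    @classmethod
    def from_dict(cls, d: dict) -> "BoardSpec":
        d = dict(d)
        if "coin_counts" in d:
            d["coin_counts"] = {int(k): int(v) for k, v in d["coin_counts"].items()}
        return cls(**d)


@dataclass
class MatchRecord:
    condition: str
    participant_policy: OpponentSpec
    seeds: dict
    participant_score: int
    ai_score: int
    pwm: int
    result: str
    move_count: int
    game_index: int

    def __post_init__(self):
        if self.pwm != self.participant_score - self.ai_score:
            raise ConfigurationError("pwm must equal participant_score - ai_score")

    def to_dict(self) -> dict:
        return {"condition": self.condition,
                "participant_policy": self.participant_policy.to_dict(),
                "seeds": dict(self.seeds),
                "participant_score": self.participant_score,
                "ai_score": self.ai_score, "pwm": self.pwm,
                "result": self.result, "move_count": self.move_count,
                "game_index": self.game_index}

    @classmethod
    def from_dict(cls, d: dict) -> "MatchRecord":
        d = dict(d)
        d["participant_policy"] = OpponentSpec.from_dict(d["participant_policy"])
        return cls(**d)


@dataclass
class ParticipantSession:
    """One simulated participant's ordered full matches (no tutorial)."""

    condition: str
    opponent: OpponentSpec
    matches: list[MatchRecord]

    @property
    def pwm_improvement(self) -> int:
        if len(self.matches) < 2:
            return 0
        return self.matches[-1].pwm - self.matches[0].pwm


@dataclass
class ConditionSummary:
    condition: str
    n: int
    target_pwm: int
    pwm_mean: float
    pwm_sd: Optional[float]
    pwm_median: float
    win_pct: float
    draw_pct: float
    loss_pct: float
    pwm_improvement_mean: float
    pwm_improvement_median: float

    def to_dict(self) -> dict:
        return {"condition": self.condition, "n": self.n,
                "target_pwm": self.target_pwm, "pwm_mean": self.pwm_mean,
                "pwm_sd": self.pwm_sd, "pwm_median": self.pwm_median,
                "win_pct": self.win_pct, "draw_pct": self.draw_pct,
                "loss_pct": self.loss_pct,
                "pwm_improvement_mean": self.pwm_improvement_mean,
                "pwm_improvement_median": self.pwm_improvement_median}


@dataclass
class KWResult:
    H: float
    df: int
    p: float
    epsilon_sq: float
    n_total: int


@dataclass
class StudyResult:
    sessions: dict[str, list[ParticipantSession]]
    master_seed: int
    games_per_session: int

    @property
    def all_matches(self) -> list[MatchRecord]:
        return [m for ss in self.sessions.values() for s in ss for m in s.matches]

    def pwm_groups(self, which: str = "last") -> dict[str, list[int]]:
        """Per-condition PWM lists: final match per session ("last", the
        default) or both matches pooled ("pooled")."""
        out: dict[str, list[int]] = {}
        for cond, sess in self.sessions.items():
            if which == "last":
                out[cond] = [s.matches[-1].pwm for s in sess]
            elif which == "pooled":
                out[cond] = [m.pwm for s in sess for m in s.matches]
            else:
                raise ConfigurationError("which must be 'last' or 'pooled'")
        return out


def _spawn_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2 ** 31)


def play_match(board: Board, condition: str, opponent: OpponentSpec,
               search_config: SearchConfig, participant_seed: int,
               search_seed: int, game_index: int = 0,
               ai_reward: Optional[RewardSpec] = None,
               seeds: Optional[dict] = None,
               figures_per_player: int = STANDARD_FIGURES) -> MatchRecord:
    """One full match: the scripted participant moves first, the AI answers
    with MCTS under the condition's True POSAS reward."""
    reward = condition_spec(condition) if ai_reward is None else ai_reward
    state = GameState.new(board, figures_per_player)
    prng = np.random.default_rng(participant_seed)
    move_count = 0
    try:
        while not state.is_terminal:
            if state.to_move == Player.PARTICIPANT:
                move = opp.act(opponent, state, prng)
            else:
                cfg = replace(search_config,
                              seed=(search_seed + 7919 * move_count) % (2 ** 31))
                move = search(state, cfg, reward)
            state = apply_move(state, move)
            move_count += 1
    except ExplorersOwlsError as err:
        raise type(err)(
            f"{err} (condition={condition}, game_index={game_index}, "
            f"participant_seed={participant_seed}, search_seed={search_seed})"
        ) from err
    p, a, res = outcome(state)
    return MatchRecord(
        condition=condition, participant_policy=opponent,
        seeds=dict(seeds or {}, participant=participant_seed, search=search_seed),
        participant_score=p, ai_score=a, pwm=p - a, result=res.value,
        move_count=move_count, game_index=game_index)


def run_session(condition: str, opponent_spec: OpponentSpec, games: int = 2,
                seed: int = 0, search_config: Optional[SearchConfig] = None,
                board_spec: Optional[BoardSpec] = None) -> ParticipantSession:
    """One simulated participant: `games` full matches in a row (default 2,
    on the standard 7x7 board with three figures per player)."""
    if games < 1:
        raise ConfigurationError("games must be >= 1")
    if condition not in CONDITIONS:
        raise ConfigurationError(f"unknown condition {condition!r}")
    search_config = search_config or SearchConfig()
    board_spec = board_spec or BoardSpec()
    ss = np.random.SeedSequence(seed)
    matches = []
    for g, child in enumerate(ss.spawn(games)):
        board_seed, part_seed, search_seed = (
            int(x) % (2 ** 31) for x in child.generate_state(3, dtype=np.uint32))
        board = board_spec.make(board_seed)
        matches.append(play_match(
            board, condition, opponent_spec, search_config,
            part_seed, search_seed, game_index=g,
            seeds={"session": seed, "board": board_seed},
            figures_per_player=board_spec.figures_per_player))
    return ParticipantSession(condition, opponent_spec, matches)


def run_study(n_per_condition: int, opponent_pool: Sequence[OpponentSpec],
              seed: int = 0, games: int = 2,
              search_config: Optional[SearchConfig] = None,
              board_spec: Optional[BoardSpec] = None,
              conditions: Sequence[str] = CONDITIONS,
              progress: bool = False) -> StudyResult:
    """Round-robin condition assignment over a seeded stream of scripted
    participants, `n_per_condition` sessions per condition."""
    if n_per_condition < 1:
        raise ConfigurationError("n_per_condition must be >= 1")
    if not opponent_pool:
        raise ConfigurationError("opponent_pool must not be empty")
    master = np.random.SeedSequence(seed)
    pool_rng = np.random.default_rng(master.spawn(1)[0])
    total = n_per_condition * len(conditions)
    session_seeds = master.spawn(total)
    iterator = range(total)
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="sessions")
        except ImportError:
            pass
    sessions: dict[str, list[ParticipantSession]] = {c: [] for c in conditions}
    for i in iterator:
        cond = conditions[i % len(conditions)]
        opponent = opponent_pool[int(pool_rng.integers(len(opponent_pool)))]
        sessions[cond].append(run_session(
            cond, opponent, games=games, seed=_spawn_seed(session_seeds[i]),
            search_config=search_config, board_spec=board_spec))
    return StudyResult(sessions=sessions, master_seed=seed,
                       games_per_session=games)


def sessions_from_records(records: Sequence[MatchRecord],
                          master_seed: int = 0,
                          games_per_session: int = 0) -> StudyResult:
    """Rebuild a StudyResult from flat match records (e.g. a JSONL log),
    grouping by condition and the logged per-session seed."""
    by_key: dict[tuple, list[MatchRecord]] = {}
    for r in records:
        by_key.setdefault((r.condition, r.seeds.get("session")), []).append(r)
    sessions: dict[str, list[ParticipantSession]] = {}
    for (cond, _), ms in by_key.items():
        ms = sorted(ms, key=lambda m: m.game_index)
        sessions.setdefault(cond, []).append(
            ParticipantSession(cond, ms[0].participant_policy, ms))
    games = games_per_session or max((len(s.matches)
                                      for ss in sessions.values() for s in ss),
                                     default=0)
    return StudyResult(sessions=sessions, master_seed=master_seed,
                       games_per_session=games)


def summarize(study: StudyResult, which: str = "last") -> list[ConditionSummary]:
    """Per-condition PWM and outcome-rate summaries.

    Outcome rates and PWM statistics use the final full match of each
    session by default; `which="pooled"` pools all matches instead.
    """
    out = []
    for cond, sess in study.sessions.items():
        if not sess:
            raise AggregationError(f"no sessions in condition {cond!r}")
        if which == "last":
            records = [s.matches[-1] for s in sess]
        elif which == "pooled":
            records = [m for s in sess for m in s.matches]
        else:
            raise ConfigurationError("which must be 'last' or 'pooled'")
        pwms = np.array([r.pwm for r in records], dtype=float)
        results = [r.result for r in records]
        improvements = np.array([s.pwm_improvement for s in sess], dtype=float)
        n = len(records)
        out.append(ConditionSummary(
            condition=cond, n=n, target_pwm=CONDITION_TARGETS[cond],
            pwm_mean=float(pwms.mean()),
            pwm_sd=float(pwms.std(ddof=1)) if n > 1 else None,
            pwm_median=float(np.median(pwms)),
            win_pct=100.0 * results.count(Result.PLAYER_WIN.value) / n,
            draw_pct=100.0 * results.count(Result.DRAW.value) / n,
            loss_pct=100.0 * results.count(Result.PLAYER_LOSS.value) / n,
            pwm_improvement_mean=float(improvements.mean()),
            pwm_improvement_median=float(np.median(improvements))))
    return out


def kruskal_wallis_epsilon2(groups: Iterable[Sequence[float]]) -> KWResult:
    """Rank-based Kruskal–Wallis H (tie-corrected) with the ε² effect size
    ``H·(n+1)/(n²−1)``; p from the chi-square approximation (df = k−1)."""
    groups = [list(g) for g in groups]
    if len(groups) < 2:
        raise ConfigurationError("kruskal_wallis_epsilon2 needs >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ConfigurationError("all groups must be non-empty")
    n = sum(len(g) for g in groups)
    if n < 3:
        raise ConfigurationError("total sample size must be >= 3")
    flat = [v for g in groups for v in g]
    if len(set(flat)) == 1:
        h, p = 0.0, 1.0  # no variation anywhere: H is 0 by definition
    else:
        h, p = sstats.kruskal(*groups)
    eps2 = epsilon_squared(float(h), n)
    return KWResult(H=float(h), df=len(groups) - 1, p=float(p),
                    epsilon_sq=eps2, n_total=n)


def epsilon_squared(h: float, n: int) -> float:
    """ε² effect size for a Kruskal–Wallis H with total sample size n."""
    return float(h) * (n + 1) / (n ** 2 - 1)


def dunn_holm(groups: Sequence[Sequence[float]],
              labels: Optional[Sequence[str]] = None) -> list[dict]:
    """Dunn's pairwise rank-sum z tests with Holm-adjusted two-sided p.

    z_ij = (mean rank_i − mean rank_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j))
    with the tie correction T = Σ(t³−t) / (12(N−1)).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [str(i) for i in range(len(groups))]
    flat = np.concatenate(groups)
    n_tot = len(flat)
    ranks = sstats.rankdata(flat)
    mean_ranks = []
    off = 0
    for g in groups:
        mean_ranks.append(ranks[off:off + len(g)].mean())
        off += len(g)
    _, counts = np.unique(flat, return_counts=True)
    tie_corr = float(((counts ** 3 - counts).sum()) / (12.0 * (n_tot - 1)))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_corr
    raw = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sstats.norm.sf(abs(z))
            raw.append({"a": labels[i], "b": labels[j], "z": float(z),
                        "p": float(p)})
    # Holm step-down adjustment
    order = np.argsort([r["p"] for r in raw])
    m = len(raw)
    prev = 0.0
    for rank, idx in enumerate(order):
        adj = min(1.0, (m - rank) * raw[idx]["p"])
        prev = max(prev, adj)
        raw[idx]["p_holm"] = prev
    return raw


def study_report(study: StudyResult, which: str = "last") -> dict:
    """Summaries + Kruskal–Wallis + Dunn–Holm pairwise tests, JSON-ready."""
    groups = study.pwm_groups(which)
    kw = kruskal_wallis_epsilon2(list(groups.values()))
    return {
        "which": which,
        "summaries": [s.to_dict() for s in summarize(study, which)],
        "kruskal_wallis": {"H": kw.H, "df": kw.df, "p": kw.p,
                           "epsilon_sq": kw.epsilon_sq, "n_total": kw.n_total},
        "pairwise_dunn_holm": dunn_holm(list(groups.values()),
                                        labels=list(groups.keys())),
    }
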