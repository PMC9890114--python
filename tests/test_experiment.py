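"""Experiment-harness tests: sessions, studies, summaries and the
rank-based statistics."""

import pytest

from explorers_owls.errors import AggregationError, ConfigurationError
from explorers_owls.experiment import (MatchRecord,
                                       ParticipantSession, StudyResult,
                                       dunn_holm, epsilon_squared,
                                       kruskal_wallis_epsilon2, run_session,
                                       run_study, sessions_from_records,
                                       summarize)
from explorers_owls.mcts import SearchConfig
from explorers_owls.opponents import OpponentSpec

FAST_SEARCH = SearchConfig(iterations=50)


def make_record(condition, pwm, game_index=0, session=0):
    p = max(pwm, 0) + 5
    return MatchRecord(condition=condition,
                       participant_policy=OpponentSpec("greedy"),
                       seeds={"session": session},
                       participant_score=p, ai_score=p - pwm, pwm=pwm,
                       result=("player_win" if pwm > 0
                               else "draw" if pwm == 0 else "player_loss"),
                       move_count=30, game_index=game_index)


def make_study(cond_to_pwms):
    sessions = {}
    for cond, pwm_pairs in cond_to_pwms.items():
        sess = []
        for i, pwms in enumerate(pwm_pairs):
            matches = [make_record(cond, p, g, session=i)
                       for g, p in enumerate(pwms)]
            sess.append(ParticipantSession(cond, OpponentSpec("greedy"), matches))
        sessions[cond] = sess
    return StudyResult(sessions=sessions, master_seed=0,
                       games_per_session=2)


# ---------------------------------------------------------------------------
# sessions and studies (fast configs: 4x4 board, 2 figures, 50 iterations)

def test_session_records_pwm_improvement(tiny_board_spec):
    session = run_session("balanced", OpponentSpec("greedy"), games=2, seed=5,
                          search_config=FAST_SEARCH, board_spec=tiny_board_spec)
    assert len(session.matches) == 2
    assert [m.game_index for m in session.matches] == [0, 1]
    assert session.pwm_improvement == session.matches[1].pwm - session.matches[0].pwm
    for m in session.matches:
        assert m.pwm == m.participant_score - m.ai_score


def test_single_game_session_has_zero_improvement(tiny_board_spec):
    session = run_session("hard", OpponentSpec("random"), games=1, seed=2,
                          search_config=FAST_SEARCH, board_spec=tiny_board_spec)
    assert session.pwm_improvement == 0


def test_session_deterministic_for_fixed_seed(tiny_board_spec):
    kw = dict(games=2, seed=11, search_config=FAST_SEARCH,
              board_spec=tiny_board_spec)
    a = run_session("easy", OpponentSpec("greedy"), **kw)
    b = run_session("easy", OpponentSpec("greedy"), **kw)
    assert [m.to_dict() for m in a.matches] == [m.to_dict() for m in b.matches]


def test_session_rejects_bad_arguments(tiny_board_spec):
    with pytest.raises(ConfigurationError):
        run_session("balanced", OpponentSpec("greedy"), games=0)
    with pytest.raises(ConfigurationError):
        run_session("medium", OpponentSpec("greedy"))


def test_study_round_robin_counts_and_determinism(tiny_board_spec):
    kw = dict(seed=3, games=1, search_config=FAST_SEARCH,
              board_spec=tiny_board_spec)
    study = run_study(2, [OpponentSpec("random")], **kw)
    assert sorted(study.sessions) == ["balanced", "easy", "hard"]
    assert all(len(s) == 2 for s in study.sessions.values())
    assert len(study.all_matches) == 6
    # single-spec pool: every session shares the participant policy
    assert {m.participant_policy for m in study.all_matches} == {OpponentSpec("random")}
    again = run_study(2, [OpponentSpec("random")], **kw)
    assert ([m.to_dict() for m in study.all_matches]
            == [m.to_dict() for m in again.all_matches])


def test_records_round_trip_through_session_rebuild(tiny_board_spec):
    study = run_study(2, [OpponentSpec("greedy")], seed=9, games=2,
                      search_config=FAST_SEARCH, board_spec=tiny_board_spec)
    rebuilt = sessions_from_records(study.all_matches)
    assert ([s.to_dict() for s in summarize(rebuilt)]
            == [s.to_dict() for s in summarize(study)])


# ---------------------------------------------------------------------------
# summaries

def test_summary_of_all_draw_condition():
    study = make_study({"balanced": [(0, 0), (0, 0), (0, 0)],
                        "easy": [(15, 15)], "hard": [(-15, -15)]})
    summary = {s.condition: s for s in summarize(study)}
    assert summary["balanced"].draw_pct == 100.0
    assert summary["balanced"].pwm_median == 0.0
    assert summary["balanced"].win_pct == 0.0


def test_summary_medians_follow_final_match_pwms():
    study = make_study({"easy": [(10, 18), (0, 18)],
                        "balanced": [(5, -1), (3, -1)],
                        "hard": [(-2, -15), (0, -15)]})
    med = {s.condition: s.pwm_median for s in summarize(study)}
    assert med == {"easy": 18.0, "balanced": -1.0, "hard": -15.0}


def test_summary_single_session_has_no_sd():
    study = make_study({"easy": [(1, 2)], "balanced": [(0, 0)],
                        "hard": [(-1, -2)]})
    for s in summarize(study):
        assert s.n == 1 and s.pwm_sd is None


def test_summary_pooled_mode_uses_both_matches():
    study = make_study({"easy": [(0, 20)], "balanced": [(0, 0)],
                        "hard": [(0, -20)]})
    last = {s.condition: s.pwm_mean for s in summarize(study, "last")}
    pooled = {s.condition: s.pwm_mean for s in summarize(study, "pooled")}
    assert last["easy"] == 20.0 and pooled["easy"] == 10.0


def test_summary_rejects_empty_condition():
    study = StudyResult(sessions={"easy": []}, master_seed=0,
                        games_per_session=2)
    with pytest.raises(AggregationError):
        summarize(study)


def test_outcome_percentages_sum_to_100(tiny_board_spec):
    study = run_study(2, [OpponentSpec("random")], seed=1, games=1,
                      search_config=FAST_SEARCH, board_spec=tiny_board_spec)
    for s in summarize(study):
        assert s.win_pct + s.draw_pct + s.loss_pct == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# rank statistics

def test_kruskal_wallis_matches_hand_ranked_example():
    # groups {1,2},{3,4},{5,6}: ranks 1..6, rank sums 3/7/11, no ties:
    # H = 12/(6*7) * (9/2 + 49/2 + 121/2) - 3*7 = 32/7
    res = kruskal_wallis_epsilon2([[1, 2], [3, 4], [5, 6]])
    assert res.H == pytest.approx(32 / 7, abs=1e-9)
    assert res.df == 2
    assert res.n_total == 6
    assert res.epsilon_sq == pytest.approx((32 / 7) * 7 / 35, abs=1e-9)


def test_kruskal_wallis_constant_groups_give_zero_effect():
    res = kruskal_wallis_epsilon2([[4, 4], [4, 4], [4, 4]])
    assert res.H == 0.0
    assert res.epsilon_sq == 0.0
    assert res.p == 1.0


def test_kruskal_wallis_needs_two_groups():
    with pytest.raises(ConfigurationError):
        kruskal_wallis_epsilon2([[1, 2, 3]])
    with pytest.raises(ConfigurationError):
        kruskal_wallis_epsilon2([[1], []])


def test_epsilon_squared_reproduces_reported_effect_size():
    # H=244 over n=311 gives 0.787, matching the reported 0.786 to H rounding
    assert round(epsilon_squared(244, 311), 3) == 0.787
    assert epsilon_squared(244, 311) == pytest.approx(0.786, abs=0.002)


def test_dunn_holm_flags_separated_groups_in_order():
    groups = [list(range(20, 30)), list(range(10, 20)), list(range(0, 10))]
    pairs = dunn_holm(groups, labels=["easy", "balanced", "hard"])
    assert {(p["a"], p["b"]) for p in pairs} == {
        ("easy", "balanced"), ("easy", "hard"), ("balanced", "hard")}
    for p in pairs:
        assert p["z"] > 0  # earlier group ranks higher
        assert p["p_holm"] <= 0.05
    z = {(p["a"], p["b"]): p["z"] for p in pairs}
    assert z[("easy", "hard")] > z[("easy", "balanced")]
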