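"""Survey distances, survey influence, Gini, word-stem pipeline and
the pair-structured correlation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import converse_align as ca
from converse_align import behavior as bh


def test_survey_distance_examples():
    assert ca.survey_distance([1, 2, 3], [1, 2, 3]) == 0.0
    assert ca.survey_distance([1, 2, 3], [2, 2, 5]) == 3.0
    with pytest.raises(ValueError, match="length"):
        ca.survey_distance([1, 2], [1, 2, 3])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(1, 7), min_size=3, max_size=3),
       st.lists(st.integers(1, 7), min_size=3, max_size=3),
       st.lists(st.integers(1, 7), min_size=3, max_size=3))
def test_survey_distance_triangle_inequality(a, b, c):
    assert ca.survey_distance(a, c) <= \
        ca.survey_distance(a, b) + ca.survey_distance(b, c) + 1e-12


def test_survey_influence_identities():
    ego, alter_pre = [1, 5, 3], [4, 1, 3]
    assert ca.survey_influence(ego, alter_pre, alter_pre) == 0.0
    assert ca.survey_influence(ego, alter_pre, ego) == \
        ca.survey_distance(ego, alter_pre)


def test_survey_influence_detects_pull_toward_ego():
    """Moving every alter halfway toward one ego's answers produces
    positive influence from that ego and none in reverse."""
    cfg = ca.SimulationConfig(group_sizes=(4,), n_controls=0,
                              n_clips=2, seed=3)
    pre, _ = ca.generate_surveys(cfg, pull=0.0, seed=4)
    ids = cfg.subject_ids()
    post = pre.copy()
    ego = ids[0]
    ego_block = pre.loc[ego]
    for alter in ids[1:]:
        moved = pre.loc[alter] + 0.5 * (ego_block - pre.loc[alter])
        post.loc[alter] = np.round(moved).to_numpy()
    tab = bh.survey_influence_table(pre, post)
    fwd = tab[tab.ego == ego]["influence"].mean()
    rev = tab[tab.alter == ego]["influence"].mean()
    assert fwd > 0
    assert fwd > rev


def test_gini_examples_and_errors():
    assert ca.gini([3, 3, 3, 3]) == pytest.approx(0.0)
    assert ca.gini([0, 1]) == pytest.approx(0.5)
    with pytest.raises(ValueError, match="negative"):
        ca.gini([-1, 2])
    with pytest.raises(ValueError, match="zero"):
        ca.gini([0, 0])


def test_gini_matches_double_sum_oracle():
    rng = np.random.default_rng(0)
    for _ in range(10):
        x = rng.integers(0, 100, size=rng.integers(2, 12)).astype(float)
        if x.sum() == 0:
            continue
        n = len(x)
        oracle = np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n *
                                                          x.mean())
        assert ca.gini(x) == pytest.approx(oracle, abs=1e-12)
    # merging two equal values leaves G unchanged
    assert ca.gini([1, 1, 1, 97]) == pytest.approx(
        np.abs(np.subtract.outer([1, 1, 1, 97], [1, 1, 1, 97])).sum()
        / (2 * 16 * 25.0))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=10),
       st.floats(0.1, 50.0))
def test_gini_scale_invariance(x, c):
    assert ca.gini(np.array(x) * c) == pytest.approx(ca.gini(x),
                                                     abs=1e-9)


def _toy_turns():
    rows = []
    tid = 0
    # 'common' passes all filters; 'narrow' fails speaker breadth;
    # 'clippy' fails clip breadth; 'scarce' folds into RAREWORD
    for clip in range(3):
        for spk in range(12):
            stems = ["common"]
            if spk < 2:
                stems.append("narrow")
            if clip == 0:
                stems.append("clippy")
            if tid % 18 == 0:
                stems.append("scarce")
            rows.append({"turn_id": tid, "speaker": f"p{spk}",
                         "group": "g0", "clip": f"clip{clip}",
                         "n_words": len(stems), "stems": " ".join(stems),
                         "status": 0.0})
            tid += 1
    return pd.DataFrame(rows)


def test_word_filters_match_hand_enumeration():
    turns = _toy_turns()
    mat = ca.word_stem_matrix(turns, min_total=5, min_speakers=10,
                              min_clips=3)
    # common: 36 uses, 12 speakers, 3 clips -> kept
    # narrow: 6 uses but only 2 speakers -> dropped
    # clippy: 12 uses, 12 speakers but 1 clip -> dropped
    # scarce: 2 uses -> RAREWORD
    assert list(mat.columns) == ["common", "RAREWORD"]
    assert mat["common"].sum() == 36
    assert mat["RAREWORD"].sum() == 2


def test_word_filters_are_idempotent():
    turns = _toy_turns()
    mat = ca.word_stem_matrix(turns, min_total=5, min_speakers=10,
                              min_clips=3)
    rebuilt = turns.copy()
    rebuilt["stems"] = [
        " ".join(np.repeat(mat.columns, mat.loc[t].to_numpy()))
        for t in rebuilt["turn_id"]]
    mat2 = ca.word_stem_matrix(rebuilt, min_total=5, min_speakers=10,
                               min_clips=3)
    pd.testing.assert_frame_equal(mat, mat2[mat.columns])


def test_word_filter_edge_thresholds():
    # a stem used 50 times by 9 speakers is excluded by speaker breadth
    rows = []
    for k in range(50):
        rows.append({"turn_id": k, "speaker": f"p{k % 9}", "group": "g",
                     "clip": f"clip{k % 4}", "n_words": 1,
                     "stems": "ninespeak", "status": 0.0})
    mat = ca.word_stem_matrix(pd.DataFrame(rows), min_total=5,
                              min_speakers=10, min_clips=3)
    assert "ninespeak" not in mat.columns


def test_word_regression_planted_and_oracle():
    rng = np.random.default_rng(5)
    n_turn = 60
    speakers = pd.Series([f"p{k % 10}" for k in range(n_turn)],
                         index=pd.Index(range(n_turn), name="turn_id"))
    cov_by_spk = {f"p{k}": (k - 4.5) / 2.87 for k in range(10)}
    cov = speakers.map(cov_by_spk)
    counts = rng.poisson(1.0, size=(n_turn, 7)).astype(float)
    # planted stem used proportionally to the covariate
    counts[:, 0] = np.clip(np.round(cov + 2 + rng.normal(0, .1, n_turn)),
                           0, None)
    mat = pd.DataFrame(counts, index=speakers.index,
                       columns=[f"w{j}" for j in range(7)])
    res = ca.word_regression(mat, cov, speakers, n_perm=200, seed=0)
    assert res.loc["w0", "beta"] > 0
    assert res.loc["w0", "p_perm"] < 0.05
    # oracle: normal equations on the same matrix
    x = np.column_stack([np.ones(n_turn), counts])
    beta = np.linalg.solve(x.T @ x, x.T @ cov.to_numpy())
    np.testing.assert_allclose(res["beta"].to_numpy(), beta[1:],
                               atol=1e-8)


def test_word_regression_null_covariate_calibrated():
    rng = np.random.default_rng(9)
    n_turn = 80
    speakers = pd.Series([f"p{k % 16}" for k in range(n_turn)],
                         index=pd.Index(range(n_turn), name="turn_id"))
    cov = speakers.map({f"p{k}": v for k, v in
                        enumerate(rng.normal(size=16))})
    mat = pd.DataFrame(rng.poisson(1.0, size=(n_turn, 5)),
                       index=speakers.index,
                       columns=[f"w{j}" for j in range(5)])
    res = ca.word_regression(mat, cov, speakers, n_perm=200, seed=1)
    assert (res["p_perm"] > 0.01).all()
    assert abs(res["beta"].mean()) < 0.5


def test_word_regression_drops_collinear():
    speakers = pd.Series(["p0", "p1", "p2", "p3"] * 5,
                         index=pd.Index(range(20), name="turn_id"))
    cov = speakers.map({"p0": -1.0, "p1": 0.0, "p2": 0.5, "p3": 0.5})
    rng = np.random.default_rng(1)
    base = rng.poisson(2.0, size=20).astype(float)
    mat = pd.DataFrame({"w0": base, "w1": 2 * base},
                       index=speakers.index)
    res = ca.word_regression(mat, cov, speakers)
    assert res["dropped_collinear"].sum() == 1


def test_session_group_design_pull_one_signs(small_config):
    pre, post = ca.generate_surveys(small_config, pull=1.0, seed=6)
    lab = pd.Series(small_config.group_labels(),
                    index=small_config.subject_ids())
    res = bh.session_group_design(pre, post, lab, n_perm=30, seed=0)
    coefs = res["coefficients"]
    # post within-group distances collapse, so the within main effect
    # (post session baseline) is negative and the interaction positive
    assert coefs["within"] < 0
    assert coefs["before_within"] > 0
    assert 0 <= res["marginal_r2"] <= 1


def test_session_group_design_missing_session_rejected(small_config):
    pre, post = ca.generate_surveys(small_config, pull=0.5, seed=6)
    lab = pd.Series(small_config.group_labels(),
                    index=small_config.subject_ids())
    table = bh.pair_distance_table(pre, post, lab)
    # simulate the guard directly: drop one session of one pair
    broken = table.drop(table.index[0])
    counts = broken.groupby("pair")["before"].nunique()
    assert (counts < 2).any()


def test_pairwise_correlation_test_identity_and_detection():
    rng = np.random.default_rng(2)
    n = 10
    ii, jj = np.tril_indices(n, k=-1)
    idx = pd.DataFrame({"i": ii, "j": jj})
    x = pd.Series(rng.normal(size=len(ii)))
    res = ca.pairwise_correlation_test(x, x, idx, list(range(n)),
                                       n_perm=100, seed=0)
    assert res["r"] == pytest.approx(1.0)
    assert res["p_two_tailed"] < 0.05
    y = pd.Series(rng.normal(size=len(ii)))
    res_null = ca.pairwise_correlation_test(x, y, idx, list(range(n)),
                                            n_perm=100, seed=0)
    assert res_null["p_two_tailed"] > 0.01


def test_group_features_gini_of_words(small_cohort):
    feats = bh.group_features(small_cohort.turns)
    assert {"group", "clip", "total_words", "gini_words"} <= \
        set(feats.columns)
    assert ((feats["gini_words"] >= 0) & (feats["gini_words"] < 1)).all()
    assert (feats["total_words"] > 0).all()
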