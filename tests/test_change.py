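"""Change-matrix regression: design construction, OLS, clustering,
whole-brain alignment."""

import numpy as np
import pandas as pd
import pytest

import converse_align as ca
from converse_align.change import vectorize_stacks
from conftest import normal_equation_betas


def _stack(values, ids, labels, clip="clip0"):
    return ca.ChangeStack(values=values, subject_ids=ids,
                          group_labels=labels, clip_id=clip)


def test_change_stack_arithmetic_and_mismatch():
    ids = list("abc")
    pre = ca.IscStack(values=np.full((2, 3, 3), 0.2), subject_ids=ids)
    post = ca.IscStack(values=np.full((2, 3, 3), 0.5), subject_ids=ids)
    ch = ca.change_stack(pre, post)
    assert np.allclose(ch.values, 0.3)
    bad = ca.IscStack(values=np.zeros((2, 3, 3)), subject_ids=list("abd"))
    with pytest.raises(ValueError, match="mismatch"):
        ca.change_stack(pre, bad)


def test_change_stack_propagates_undefined():
    ids = list("abc")
    pre = np.zeros((1, 3, 3))
    pre[0, 0, 1] = np.nan
    ch = ca.change_stack(ca.IscStack(values=pre, subject_ids=ids),
                         ca.IscStack(values=np.ones((1, 3, 3)),
                                     subject_ids=ids))
    assert np.isnan(ch.values[0, 0, 1])


def test_design_two_groups_plus_control_combinatorics():
    labels = ["g1", "g1", "g2", "g2", "control"]
    d = ca.build_design(labels, ["clip0"], mode="per_group")
    assert d.matrix.shape == (10, 3)           # C(5,2) pairs
    assert d.names == ["intercept", "group:g1", "group:g2"]
    assert d.matrix[:, 1].sum() == 1 and d.matrix[:, 2].sum() == 1
    assert np.all(d.matrix[:, 0] == 1)


def test_design_all_groups_mode_sums():
    labels = ["g1", "g1", "g2", "g2", "control"]
    d = ca.build_design(labels, ["clip0"], mode="all_groups")
    assert d.names == ["intercept", "any_group"]
    assert d.matrix[:, 1].sum() == 2


def test_design_worked_toy_layout_two_groups_of_four():
    # two groups x four participants: C(8,2)=28 pair rows, C(4,2)=6
    # ones per group column
    labels = ["g1"] * 4 + ["g2"] * 4
    d = ca.build_design(labels, ["clip0"], mode="per_group")
    assert d.matrix.shape == (28, 3)
    assert d.matrix[:, 1].sum() == 6 and d.matrix[:, 2].sum() == 6


def test_design_concatenates_clips_and_rejects_singletons():
    labels = ["g1", "g1", "g2"]
    with pytest.raises(ValueError, match="g2"):
        ca.build_design(labels, ["clip0"])
    d = ca.build_design(["g1", "g1", "control"], ["c0", "c1", "c2"])
    assert d.matrix.shape == (9, 2)


def test_intercept_only_regression_recovers_mean():
    rng = np.random.default_rng(0)
    vals = rng.normal(0.1, 0.2, (4, 5, 5))
    vals = (vals + vals.transpose(0, 2, 1)) / 2
    ids = list("abcde")
    st = _stack(vals, ids, ["control"] * 5)
    d = ca.build_design(["control"] * 5, ["clip0"])
    maps = ca.fit_pairwise_regression([st], d)
    ii, jj = np.tril_indices(5, k=-1)
    np.testing.assert_allclose(maps.betas[:, 0],
                               vals[:, ii, jj].mean(axis=1), atol=1e-10)


def test_regression_matches_normal_equation_oracle():
    rng = np.random.default_rng(12)
    for trial in range(10):
        n = 9
        labels = ["g1"] * 3 + ["g2"] * 3 + ["control"] * 3
        vals = rng.normal(size=(6, n, n))
        vals = (vals + vals.transpose(0, 2, 1)) / 2
        st = _stack(vals, [f"s{i}" for i in range(n)], labels)
        d = ca.build_design(labels, ["clip0"])
        maps = ca.fit_pairwise_regression([st], d)
        y = vectorize_stacks([st], d)
        oracle = normal_equation_betas(d.matrix, y).T
        np.testing.assert_allclose(maps.betas, oracle, atol=1e-8)


def test_group_beta_recovers_planted_convergence(small_cohort,
                                                 small_config):
    changes = [ca.change_stack(ca.isc_matrix(p), ca.isc_matrix(q))
               for p, q in zip(small_cohort.bold_pre,
                               small_cohort.bold_post)]
    labels = small_cohort.group_labels
    d = ca.build_design(labels, [c.clip_id for c in changes],
                        subject_ids=small_cohort.subject_ids)
    maps = ca.fit_pairwise_regression(changes, d)
    mask = small_config.affected_mask()
    db = small_config.b_group_post - small_config.b_group_pre
    got = maps.betas[mask][:, 1:].mean()
    assert got == pytest.approx(db, abs=0.08)
    assert abs(maps.betas[mask][:, 0].mean()) < 0.05      # intercept ~ 0
    assert abs(maps.betas[~mask][:, 1:].mean()) < 0.05


def test_rank_deficient_design_rejected_with_names():
    labels = ["g1", "g1", "control"]
    d = ca.build_design(labels, ["clip0"])
    d.matrix[:, 1] = d.matrix[:, 0]
    st = _stack(np.zeros((1, 3, 3)), list("abc"), labels)
    with pytest.raises(ValueError, match="rank deficient"):
        ca.fit_pairwise_regression([st], d)


def test_novel_clip_regression_constant_matrix():
    ids = list("abcd")
    labels = ["g1", "g1", "g2", "g2"]
    post = ca.IscStack(values=np.full((3, 4, 4), 0.4), subject_ids=ids,
                       group_labels=labels)
    d = ca.build_design(labels, ["clip0"])
    maps = ca.novel_clip_regression([post], d)
    assert maps.model_tag == "novel_post"
    np.testing.assert_allclose(maps.betas[:, 0], 0.4, atol=1e-10)
    np.testing.assert_allclose(maps.betas[:, 1:], 0.0, atol=1e-10)


def test_novel_clip_regression_recovers_group_signal():
    cfg = ca.SimulationConfig(group_sizes=(4, 4), n_controls=2,
                              grid_shape=(2, 2, 2), n_timepoints=600,
                              n_clips=1, a_shared=0.1, b_group_pre=0.0,
                              b_group_post=0.25, affected_block=(2, 2, 2),
                              seed=21)
    _, post = ca.generate_bold(cfg)
    stack = ca.isc_matrix(post[0])
    d = ca.build_design(post[0].group_labels, ["clip0"],
                        subject_ids=post[0].subject_ids)
    maps = ca.novel_clip_regression([stack], d)
    assert maps.betas[:, 1:].mean() == pytest.approx(0.25, abs=0.07)


def _perm_result(p):
    return ca.PermutationResult(p_two_tailed=p, names=["intercept", "g"],
                                n_permutations=100, seed=0)


def test_cluster_correct_planted_block():
    grid = (6, 6, 6)
    v = int(np.prod(grid))
    p = np.ones((v, 2))
    betas = np.zeros((v, 2))
    mask = np.zeros(grid, dtype=bool)
    mask[:4, :4, :4] = True
    flat = mask.reshape(-1)
    p[flat, 1] = 0.001
    betas[flat, 1] = 0.5
    maps = ca.RegressionMaps(betas=betas, names=["intercept", "g"],
                             grid_shape=grid)
    tab = ca.cluster_correct(maps, _perm_result(p), min_size=32)
    assert len(tab) == 1
    assert tab.iloc[0]["n_voxels"] == 64
    assert tab.iloc[0]["predictor"] == "g"
    assert tab.iloc[0]["beta_mean"] == pytest.approx(0.5)


def test_cluster_correct_min_size_filters():
    grid = (10, 10, 10)
    v = 1000
    p = np.ones((v, 2))
    betas = np.zeros((v, 2))
    m = np.zeros(grid, dtype=bool)
    m[:5, :3, :2] = True           # 30 voxels, below min_size
    m[5:10, 6:10, 8:10] = True     # 40 voxels, survives
    flat = m.reshape(-1)
    p[flat, 1] = 0.001
    betas[flat, 1] = 1.0
    maps = ca.RegressionMaps(betas=betas, names=["intercept", "g"],
                             grid_shape=grid)
    tab = ca.cluster_correct(maps, _perm_result(p), min_size=32)
    assert len(tab) == 1 and tab.iloc[0]["n_voxels"] == 40


def test_cluster_correct_empty_when_nothing_suprathreshold():
    maps = ca.RegressionMaps(betas=np.ones((8, 2)),
                             names=["intercept", "g"], grid_shape=(2, 2, 2))
    tab = ca.cluster_correct(maps, _perm_result(np.ones((8, 2))))
    assert tab.empty


def test_cluster_correct_requires_grid():
    maps = ca.RegressionMaps(betas=np.ones((8, 2)),
                             names=["intercept", "g"])
    with pytest.raises(ValueError, match="grid"):
        ca.cluster_correct(maps, _perm_result(np.ones((8, 2))))


def test_whole_brain_alignment_positive_part_only():
    ids = list("abc")
    vals = np.full((4, 3, 3), -0.5)
    vals[:3, 0, 1] = vals[:3, 1, 0] = 0.1
    st = _stack(vals, ids, ["g"] * 3)
    tab = ca.whole_brain_alignment(st)
    row = tab[(tab.subj_i == "b") & (tab.subj_j == "a")]
    assert row["alignment"].iloc[0] == pytest.approx(0.3)
    others = tab[~((tab.subj_i == "b") & (tab.subj_j == "a"))]
    assert (others["alignment"] == 0).all()


def test_whole_brain_alignment_monotone_in_single_voxel():
    rng = np.random.default_rng(2)
    vals = rng.normal(size=(5, 4, 4))
    vals = (vals + vals.transpose(0, 2, 1)) / 2
    ids = list("abcd")
    base = ca.whole_brain_alignment(_stack(vals.copy(), ids, ["g"] * 4))
    vals[2, 1, 0] += 0.7
    vals[2, 0, 1] += 0.7
    bumped = ca.whole_brain_alignment(_stack(vals, ids, ["g"] * 4))
    assert (bumped["alignment"] >= base["alignment"] - 1e-12).all()
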