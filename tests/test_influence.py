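"""Directed neural influence and its centrality regression."""

import numpy as np
import pandas as pd
import pytest

import converse_align as ca
from converse_align.change import vectorize_stacks
from conftest import normal_equation_betas


def _sessions(seed=0, n=4, v=8, t=300, labels=None):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    labels = labels or ["g"] * n
    mk = lambda: ca.BoldSession(data=rng.standard_normal((n, v, t)),
                                subject_ids=ids, group_labels=labels)
    return mk(), mk()


def test_influence_zero_when_alter_unchanged():
    pre, _ = _sessions(seed=1)
    st = ca.influence_stack(ca.isc_matrix(pre),
                            ca.cross_isc_matrix(pre, pre))
    off = ~np.eye(pre.n_subjects, dtype=bool)
    assert np.allclose(st.values[:, off], 0.0, atol=1e-12)


def test_influence_when_alter_copies_ego():
    pre, post = _sessions(seed=2)
    post.data[1] = pre.data[0]        # alter s1 lands on ego s0's start
    ipre = ca.isc_matrix(pre)
    st = ca.influence_stack(ipre, ca.cross_isc_matrix(pre, post))
    np.testing.assert_allclose(st.values[:, 0, 1],
                               1.0 - ipre.values[:, 0, 1], atol=1e-10)


def test_influence_matches_pairwise_isc_loop():
    pre, post = _sessions(seed=3, n=3, v=2, t=40)
    st = ca.influence_stack(ca.isc_matrix(pre),
                            ca.cross_isc_matrix(pre, post))
    for v in range(2):
        for e in range(3):
            for a in range(3):
                if e == a:
                    assert np.isnan(st.values[v, e, a])
                    continue
                oracle = (ca.pairwise_isc(pre.data[e, v], post.data[a, v])
                          - ca.pairwise_isc(pre.data[e, v],
                                            pre.data[a, v]))
                assert st.values[v, e, a] == pytest.approx(oracle,
                                                           abs=1e-10)


def test_injected_influence_is_directional():
    cfg = ca.SimulationConfig(group_sizes=(3, 3), n_controls=0,
                              grid_shape=(2, 2, 2), n_timepoints=500,
                              n_clips=1, a_shared=0.0, b_group_pre=0.0,
                              b_group_post=0.0, influence_weight=0.25,
                              seed=6)
    coh = ca.generate_cohort(cfg, influence_pairs=[("sub000", "sub001")])
    st = ca.influence_stack(
        ca.isc_matrix(coh.bold_pre[0]),
        ca.cross_isc_matrix(coh.bold_pre[0], coh.bold_post[0]))
    fwd = np.nanmean(st.values[:, 0, 1])
    rev = np.nanmean(st.values[:, 1, 0])
    assert fwd == pytest.approx(0.5, abs=0.1)       # sqrt(w)
    assert abs(rev) < 0.1


def test_whole_brain_influence_positive_part():
    ids = list("abc")
    vals = np.full((6, 3, 3), -0.3)
    vals[:5, 0, 1] = 0.2
    st = ca.InfluenceStack(values=vals, subject_ids=ids, symmetric=False)
    tab = ca.whole_brain_influence(st)
    row = tab[(tab.ego == "a") & (tab.alter == "b")]
    assert row["influence"].iloc[0] == pytest.approx(1.0)
    rest = tab[~((tab.ego == "a") & (tab.alter == "b"))]
    assert (rest["influence"] == 0).all()


def test_whole_brain_influence_monotone_in_w():
    means = []
    for w in (0.0, 0.1, 0.3):
        cfg = ca.SimulationConfig(group_sizes=(3,), n_controls=0,
                                  grid_shape=(2, 2, 2), n_timepoints=300,
                                  n_clips=1, a_shared=0.0,
                                  b_group_pre=0.0, b_group_post=0.0,
                                  influence_weight=w, seed=9)
        coh = ca.generate_cohort(cfg,
                                 influence_pairs=[("sub000", "sub001")])
        st = ca.influence_stack(
            ca.isc_matrix(coh.bold_pre[0]),
            ca.cross_isc_matrix(coh.bold_pre[0], coh.bold_post[0]))
        tab = ca.whole_brain_influence(st)
        means.append(tab[(tab.ego == "sub000") & (tab.alter == "sub001")]
                     ["influence"].iloc[0])
    assert means[0] < means[1] < means[2]


def _centrality_frame(ids, values):
    return pd.DataFrame({"pca": values}, index=ids)


def test_centrality_design_same_group_ordered_pairs_only():
    labels = ["g1", "g1", "g2", "g2", "control"]
    ids = [f"s{i}" for i in range(5)]
    cent = _centrality_frame(ids, [1.0, 2.0, 3.0, 4.0, 5.0])
    d = ca.build_centrality_design(labels, ["c0"], cent, ids)
    # 2 ordered pairs per 2-member group, both triangles
    assert d.matrix.shape[0] == 4
    assert d.ordered
    assert d.names == ["intercept", "ego:pca", "alter:pca"]
    # ego and alter columns are transposes of each other over pairs
    pairs = list(zip(d.pair_index.i, d.pair_index.j))
    assert set(pairs) == {(0, 1), (1, 0), (2, 3), (3, 2)}


def test_constant_centrality_rejected_as_rank_deficient():
    labels = ["g1", "g1", "g1"]
    ids = list("abc")
    cent = _centrality_frame(ids, [2.0, 2.0, 2.0])
    d = ca.build_centrality_design(labels, ["c0"], cent, ids)
    vals = np.random.default_rng(0).normal(size=(2, 3, 3))
    st = ca.InfluenceStack(values=vals, subject_ids=ids,
                           group_labels=labels, clip_id="c0",
                           symmetric=False)
    with pytest.raises(ValueError, match="rank deficient"):
        ca.fit_influence_regression([st], d)


def test_influence_regression_matches_normal_equations():
    rng = np.random.default_rng(31)
    labels = ["g1"] * 4 + ["g2"] * 4
    ids = [f"s{i}" for i in range(8)]
    cent = _centrality_frame(ids, rng.normal(size=8))
    d = ca.build_centrality_design(labels, ["c0"], cent, ids)
    vals = rng.normal(size=(5, 8, 8))
    st = ca.InfluenceStack(values=vals, subject_ids=ids,
                           group_labels=labels, clip_id="c0",
                           symmetric=False)
    maps = ca.fit_influence_regression([st], d)
    y = vectorize_stacks([st], d)
    oracle = normal_equation_betas(d.matrix, y).T
    np.testing.assert_allclose(maps.betas, oracle, atol=1e-8)


def test_alter_centrality_effect_recovered():
    """Alters whose centrality is high receive stronger injected
    imitation; the alter-centrality beta must come out positive."""
    hits = 0
    n_seeds = 10
    for seed in range(n_seeds):
        cfg = ca.SimulationConfig(group_sizes=(4,), n_controls=0,
                                  grid_shape=(2, 2, 1),
                                  n_timepoints=250, n_clips=1,
                                  a_shared=0.0, b_group_pre=0.0,
                                  b_group_post=0.0, seed=100 + seed)
        pre, post = ca.generate_bold(cfg)
        ids = pre[0].subject_ids
        cvals = np.array([0.0, 0.5, 1.0, 2.0])
        # imitation strength grows with the alter's centrality
        for a, w in zip(range(1, 4), (0.05, 0.15, 0.4)):
            post[0] = ca.inject_influence(pre[0], post[0], ids[0],
                                          ids[a], w, seed=seed * 7 + a)
        st = ca.influence_stack(ca.isc_matrix(pre[0]),
                                ca.cross_isc_matrix(pre[0], post[0]))
        cent = _centrality_frame(ids, cvals)
        d = ca.build_centrality_design(pre[0].group_labels, ["clip0"],
                                       cent, ids)
        maps = ca.fit_influence_regression([st], d)
        hits += maps.betas[:, d.names.index("alter:pca")].mean() > 0
    assert hits >= 9
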