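"""End-to-end statistical validation studies on synthetic cohorts.

Each function runs one self-contained study — oracle equivalence of the
pair regressions, permutation type-I calibration, planted-effect
recovery, influence directionality, closed-form graph metrics, the
behavioral layer, pipeline determinism — and returns a flat dict of
measured numbers.  The studies are what the test suite asserts on and
what the analysis drivers report; they use the synthetic generator's
known ground truth throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import behavior as bh
from . import change as ch
from . import influence as infl
from . import network as net
from . import simulate as sim
from .isc import cross_isc_matrix, isc_matrix
from .io import RunConfig, run_full_pipeline

__all__ = [
    "ols_oracle_equivalence", "permutation_calibration",
    "permutation_exhaustive_agreement", "effect_recovery",
    "influence_directionality", "graph_metric_checks",
    "behavioral_checks", "pipeline_determinism",
]


def _normal_equations(x, y):
    return np.linalg.solve(x.T @ x, x.T @ y)


def ols_oracle_equivalence(n_instances: int = 50, seed: int = 0) -> dict:
    """Max |beta difference| between the package's pair regressions and
    a closed-form normal-equation solve, over random small instances.

    Cycles through the change model, the novel-clip model, the
    centrality influence model and the word-stem model.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in range(n_instances):
        kind = k % 4
        if kind in (0, 1):
            labels = ["g1"] * 3 + ["g2"] * 3 + ["control"] * 2
            n = len(labels)
            vals = rng.normal(size=(4, n, n))
            vals = (vals + vals.transpose(0, 2, 1)) / 2
            ids = [f"s{i}" for i in range(n)]
            design = ch.build_design(labels, ["c0"], subject_ids=ids)
            stack = ch.ChangeStack(values=vals, subject_ids=ids,
                                   group_labels=labels, clip_id="c0")
            maps = (ch.fit_pairwise_regression([stack], design)
                    if kind == 0 else
                    ch.novel_clip_regression([stack], design))
            y = ch.vectorize_stacks([stack], design)
        elif kind == 2:
            labels = ["g1"] * 4 + ["g2"] * 4
            n = len(labels)
            ids = [f"s{i}" for i in range(n)]
            cent = pd.DataFrame({"pca": rng.normal(size=n)}, index=ids)
            design = infl.build_centrality_design(labels, ["c0"], cent,
                                                  ids)
            vals = rng.normal(size=(3, n, n))
            stack = infl.InfluenceStack(values=vals, subject_ids=ids,
                                        group_labels=labels,
                                        clip_id="c0", symmetric=False)
            maps = infl.fit_influence_regression([stack], design)
            y = ch.vectorize_stacks([stack], design)
        else:
            n_turn, n_stem = 40, 6
            speakers = pd.Series([f"p{t % 8}" for t in range(n_turn)],
                                 index=pd.Index(range(n_turn),
                                                name="turn_id"))
            cov = speakers.map({f"p{i}": v for i, v in
                                enumerate(rng.normal(size=8))})
            mat = pd.DataFrame(
                rng.poisson(1.0, size=(n_turn, n_stem)) + 0.0,
                index=speakers.index,
                columns=[f"w{j}" for j in range(n_stem)])
            mat += rng.normal(0, 0.01, mat.shape)   # break exact ties
            res = bh.word_regression(mat, cov, speakers)
            x = np.column_stack([np.ones(n_turn), mat.to_numpy()])
            oracle = _normal_equations(x, cov.to_numpy())[1:]
            worst = max(worst, float(np.max(np.abs(
                res["beta"].to_numpy() - oracle))))
            continue
        oracle = _normal_equations(design.matrix, y).T
        worst = max(worst, float(np.max(np.abs(maps.betas - oracle))))
    return {"max_abs_beta_deviation": worst, "n_instances": n_instances}


def _null_cohort(seed: int, n_subjects: int = 20, n_groups: int = 4,
                 n_voxels: int = 500, t: int = 200):
    size = n_subjects // n_groups
    cfg = sim.SimulationConfig(
        group_sizes=(size,) * n_groups,
        n_controls=n_subjects - size * n_groups,
        grid_shape=(n_voxels, 1, 1), n_timepoints=t, n_clips=1,
        a_shared=0.1, b_group_pre=0.0, b_group_post=0.0, seed=seed)
    pre, post = sim.generate_bold(cfg)
    chg = ch.change_stack(isc_matrix(pre[0]), isc_matrix(post[0]))
    design = ch.build_design(pre[0].group_labels, ["clip0"],
                             mode="all_groups",
                             subject_ids=pre[0].subject_ids)
    return chg, design


def permutation_calibration(seed: int = 0, n_voxels: int = 500,
                            n_perm: int = 1000, alpha: float = 0.05
                            ) -> dict:
    """Empirical type-I error of the subject-wise permutation test on a
    null cohort (no group signal in either session): the fraction of
    voxels whose same-group p-value falls below alpha."""
    chg, design = _null_cohort(seed, n_voxels=n_voxels)
    res = ch.subjectwise_permutation([chg], design, n_perm=n_perm,
                                     seed=seed + 1)
    p = res.p_two_tailed[:, design.names.index("any_group")]
    return {"type_i_error": float((p < alpha).mean()),
            "alpha": alpha, "n_voxels": n_voxels, "n_perm": n_perm}


def permutation_exhaustive_agreement(seed: int = 0, n_voxels: int = 60,
                                     n_perm: int = 2000) -> dict:
    """Sampled permutation p-values vs the exhaustive 720-relabeling
    enumeration for a 6-subject cohort.  Reports the fraction of voxels
    whose sampled p lies within twice its binomial Monte-Carlo standard
    error of the exhaustive p."""
    chg, design = _null_cohort(seed + 3, n_subjects=6, n_groups=2,
                               n_voxels=n_voxels, t=120)
    ex = ch.subjectwise_permutation([chg], design, exhaustive=True)
    sam = ch.subjectwise_permutation([chg], design, n_perm=n_perm,
                                     seed=seed + 4)
    k = design.names.index("any_group")
    pe, ps = ex.p_two_tailed[:, k], sam.p_two_tailed[:, k]
    tol = 2.0 * np.sqrt(pe * (1.0 - pe) / n_perm) + 2.0 / n_perm
    return {"n_exhaustive": ex.n_permutations,
            "frac_within_mc_error": float((np.abs(ps - pe) <= tol)
                                          .mean()),
            "max_abs_p_gap": float(np.max(np.abs(ps - pe))),
            "n_voxels": n_voxels}


def effect_recovery(seed: int = 0, n_seeds: int = 100,
                    delta_b: float = 0.3, t: int = 400,
                    n_perm: int = 300) -> dict:
    """Planted group-convergence recovery over many simulated cohorts.

    Each cohort plants a convergence effect of size
    ``delta_b = b_post - b_pre`` in a contiguous 4x4x4 voxel block of a
    6x6x6 grid; the study reports the across-seed mean group beta at
    affected voxels (with its standard error) and the fraction of
    cohorts in which the corrected cluster analysis recovers a cluster
    covering at least 80% of the planted block.
    """
    rng = np.random.default_rng(seed)
    betas, overlaps = [], []
    for s in range(n_seeds):
        cfg = sim.SimulationConfig(
            group_sizes=(4, 4, 4), n_controls=2, grid_shape=(6, 6, 6),
            n_timepoints=t, n_clips=1, a_shared=0.1, b_group_pre=0.0,
            b_group_post=delta_b, affected_block=(4, 4, 4),
            seed=int(rng.integers(1 << 30)))
        pre, post = sim.generate_bold(cfg)
        chg = ch.change_stack(isc_matrix(pre[0]), isc_matrix(post[0]))
        design = ch.build_design(pre[0].group_labels, ["clip0"],
                                 subject_ids=pre[0].subject_ids)
        maps = ch.fit_pairwise_regression([chg], design)
        mask = cfg.affected_mask()
        betas.append(maps.betas[mask][:, 1:].mean())
        perm = ch.subjectwise_permutation([chg], design, n_perm=n_perm,
                                          seed=int(rng.integers(1 << 30)))
        clusters = ch.cluster_correct(maps, perm,
                                      grid_shape=cfg.grid_shape,
                                      cluster_forming_p=0.01,
                                      min_size=32)
        planted = set(np.nonzero(mask)[0])
        best = 0.0
        for vox in clusters.loc[clusters.sign == "positive",
                                "voxel_indices"]:
            got = {int(v) for v in vox.split(",")}
            best = max(best, len(got & planted) / len(planted))
        overlaps.append(best)
    betas = np.asarray(betas)
    se = betas.std(ddof=1) / np.sqrt(n_seeds)
    return {"mean_group_beta": float(betas.mean()),
            "se_group_beta": float(se),
            "true_delta_b": delta_b,
            "beta_within_3se": float(abs(betas.mean() - delta_b)
                                     <= 3 * se + 1e-12),
            "cluster_recovery_rate": float(np.mean(
                [o >= 0.8 for o in overlaps])),
            "n_seeds": n_seeds}


def influence_directionality(seed: int = 0, w: float = 0.25,
                             t: int = 400) -> dict:
    """Directional detection of injected ego -> alter imitation.

    One ordered pair receives imitation of weight ``w``; the study
    reports mean influence in the injected direction (expected
    ``sqrt(w)``), in the reverse direction, the 3-sigma null band from
    all untouched ordered pairs, and whole-brain influence for
    ``w in {0, 0.1, 0.3}`` (monotonicity check).
    """
    cfg = sim.SimulationConfig(
        group_sizes=(3, 3), n_controls=0, grid_shape=(4, 4, 2),
        n_timepoints=t, n_clips=1, a_shared=0.0, b_group_pre=0.0,
        b_group_post=0.0, influence_weight=w, seed=seed)
    coh = sim.generate_cohort(cfg, influence_pairs=[("sub000",
                                                     "sub001")])
    st = infl.influence_stack(
        isc_matrix(coh.bold_pre[0]),
        cross_isc_matrix(coh.bold_pre[0], coh.bold_post[0]))
    fwd = float(np.nanmean(st.values[:, 0, 1]))
    rev = float(np.nanmean(st.values[:, 1, 0]))
    n = st.values.shape[1]
    null_means = [np.nanmean(st.values[:, e, a])
                  for e in range(n) for a in range(n)
                  if e != a and (e, a) != (0, 1)]
    null_sd = float(np.std(null_means, ddof=1))
    wb = {}
    for wk in (0.0, 0.1, 0.3):
        cfgk = sim.SimulationConfig(
            group_sizes=(3,), n_controls=0, grid_shape=(4, 4, 2),
            n_timepoints=t, n_clips=1, a_shared=0.0, b_group_pre=0.0,
            b_group_post=0.0, influence_weight=wk, seed=seed + 5)
        cohk = sim.generate_cohort(
            cfgk, influence_pairs=[("sub000", "sub001")])
        stk = infl.influence_stack(
            isc_matrix(cohk.bold_pre[0]),
            cross_isc_matrix(cohk.bold_pre[0], cohk.bold_post[0]))
        tab = infl.whole_brain_influence(stk)
        wb[wk] = float(tab[(tab.ego == "sub000")
                           & (tab.alter == "sub001")]
                       ["influence"].iloc[0])
    return {"influence_forward": fwd, "influence_reverse": rev,
            "expected_forward": float(np.sqrt(w)),
            "null_band_3sd": 3.0 * null_sd,
            "whole_brain_w0": wb[0.0], "whole_brain_w01": wb[0.1],
            "whole_brain_w03": wb[0.3],
            "monotone_in_w": float(wb[0.0] < wb[0.1] < wb[0.3])}


def graph_metric_checks(seed: int = 0, n_graphs: int = 20) -> dict:
    """Closed-form constraint/brokerage values on canonical graphs plus
    the worst deviation from a literal double-sum evaluation of Burt's
    formula on random digraphs."""
    import networkx as nx

    def undirected(edges):
        g = nx.DiGraph()
        for u, v in edges:
            g.add_edge(u, v)
            g.add_edge(v, u)
        return g

    dyad = net.burt_constraint(undirected([(0, 1)]))
    tri = net.burt_constraint(undirected([(0, 1), (1, 2), (0, 2)]))
    star = net.burt_constraint(undirected([(0, i)
                                           for i in range(1, 5)]))
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_graphs):
        n = int(rng.integers(4, 10))
        g = sim.generate_network(n, model="random-directed",
                                 seed=int(rng.integers(1 << 30)), p=0.5)
        got = net.burt_constraint(g)["constraint"]
        und = g.to_undirected()
        for i in und.nodes:
            nbrs = list(und.neighbors(i))
            if not nbrs:
                continue
            def p(u, v):
                nu = list(und.neighbors(u))
                return 1.0 / len(nu) if v in nu else 0.0
            c = sum((p(i, j) + sum(p(i, q) * p(q, j)
                                   for q in und.nodes
                                   if q not in (i, j))) ** 2
                    for j in nbrs)
            worst = max(worst, abs(got[i] - c))
    return {"dyad_constraint": float(dyad["constraint"].iloc[0]),
            "dyad_brokerage": float(dyad["brokerage"].iloc[0]),
            "triangle_constraint": float(tri["constraint"].iloc[0]),
            "triangle_brokerage": float(tri["brokerage"].iloc[0]),
            "star_center_constraint": float(star.loc[0, "constraint"]),
            "star_center_brokerage": float(star.loc[0, "brokerage"]),
            "constraint_oracle_max_dev": float(worst),
            "n_graphs": n_graphs}


def behavioral_checks(seed: int = 0) -> dict:
    """Gini closed forms, the pull=1 survey collapse, word-filter hand
    enumeration, and the survey/neural influence coupling on a cohort
    with matched injected imitation."""
    g_two_point = bh.gini([0.0, 1.0])
    x = np.array([3.0, 1.0, 4.0, 1.5])
    scale_gap = abs(bh.gini(7.5 * x) - bh.gini(x))

    cfg = sim.SimulationConfig(group_sizes=(4, 4), n_controls=1,
                               n_clips=3, seed=seed + 2)
    pre, post = sim.generate_surveys(cfg, pull=1.0, seed=seed + 2)
    lab = pd.Series(cfg.group_labels(), index=cfg.subject_ids())
    t = bh.pair_distance_table(pre, post, lab)
    collapse = float(t.loc[(t.within == 1) & (t.before == 0),
                           "distance"].abs().max())

    rows, tid = [], 0
    for clip in range(3):
        for spk in range(12):
            stems = ["common"] + (["narrow"] if spk < 2 else []) \
                + (["clippy"] if clip == 0 else []) \
                + (["scarce"] if tid % 18 == 0 else [])
            rows.append({"turn_id": tid, "speaker": f"p{spk}",
                         "group": "g0", "clip": f"clip{clip}",
                         "n_words": len(stems),
                         "stems": " ".join(stems), "status": 0.0})
            tid += 1
    mat = bh.word_stem_matrix(pd.DataFrame(rows), min_total=5,
                              min_speakers=10, min_clips=3)
    filters_ok = float(list(mat.columns) == ["common", "RAREWORD"]
                       and mat["common"].sum() == 36
                       and mat["RAREWORD"].sum() == 2)

    # matched neural + survey imitation: in each group every alter
    # moves halfway toward the first member (the ego) on both channels
    cfg2 = sim.SimulationConfig(
        group_sizes=(4, 4), n_controls=0, grid_shape=(3, 3, 2),
        n_timepoints=300, n_clips=1, a_shared=0.0, b_group_pre=0.0,
        b_group_post=0.0, influence_weight=0.25, seed=seed + 9)
    ids = cfg2.subject_ids()
    pairs = [(ids[0], ids[k]) for k in (1, 2, 3)] \
        + [(ids[4], ids[k]) for k in (5, 6, 7)]
    coh = sim.generate_cohort(cfg2, pull=0.0, influence_pairs=pairs)
    spre, _ = sim.generate_surveys(cfg2, pull=0.0, seed=seed + 10)
    spost = spre.copy()
    for ego, alter in pairs:
        moved = spre.loc[alter] + 0.5 * (spre.loc[ego].to_numpy()
                                         - spre.loc[alter])
        spost.loc[alter] = np.round(moved).to_numpy()
    st = infl.influence_stack(
        isc_matrix(coh.bold_pre[0]),
        cross_isc_matrix(coh.bold_pre[0], coh.bold_post[0]))
    wb = infl.whole_brain_influence(st).set_index(["ego", "alter"])
    sv = bh.survey_influence_table(
        spre, spost, group_labels=pd.Series(cfg2.group_labels(),
                                            index=ids),
        same_group_only=True).set_index(["ego", "alter"])
    joined = wb.join(sv, how="inner", lsuffix="_neural",
                     rsuffix="_survey").dropna()
    r = float(np.corrcoef(joined["influence_neural"],
                          joined["influence_survey"])[0, 1])
    return {"gini_two_point": float(g_two_point),
            "gini_scale_invariance_gap": float(scale_gap),
            "pull1_within_post_distance": collapse,
            "word_filters_match_enumeration": filters_ok,
            "survey_neural_influence_corr": r,
            "n_ordered_pairs": int(len(joined))}


def pipeline_determinism(seed: int = 0, tmpdir=None) -> dict:
    """Two full pipeline runs on the same (cohort, config): summary
    tables must hash identically."""
    import tempfile
    from pathlib import Path
    cfg = sim.SimulationConfig(group_sizes=(3, 3), n_controls=1,
                               grid_shape=(3, 3, 3), n_timepoints=60,
                               n_clips=2, a_shared=0.1, b_group_pre=0.0,
                               b_group_post=0.2, affected_block=(2, 2, 2),
                               seed=seed)
    coh = sim.generate_cohort(cfg, pull=0.5)
    rc = RunConfig(n_perm=50, seed=seed, behavior_n_perm=5,
                   min_cluster_size=4)
    base = Path(tmpdir) if tmpdir else Path(tempfile.mkdtemp())
    r1 = run_full_pipeline(coh, rc, base / "run1")
    r2 = run_full_pipeline(coh, rc, base / "run2")
    return {"identical_hashes": float(r1["hashes"] == r2["hashes"]),
            "n_tables": len(r1["hashes"])}
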