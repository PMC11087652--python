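"""Behavioral and linguistic companions to the neural analyses.

Covers: city-block distances between survey answer vectors and the
session x within/between-group mixed model on them; directed survey
influence (the behavioral analogue of neural influence); Gini
inequality of turn-taking, centrality and perceived status; the
word-stem filtering pipeline and word-level OLS regressions; and a
subject-wise permutation correlation test for pair-structured data.

Mixed-effects fits (random intercepts for participant pairs) are
delegated to statsmodels' MixedLM behind one small contract; the
bespoke part here is the permutation wrapper producing marginal-R2 and
coefficient p-values by shuffling the dependent variable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .simulate import CONTROL_LABEL

__all__ = [
    "survey_distance", "pair_distance_table", "session_group_design",
    "survey_influence", "survey_influence_table", "gini",
    "word_stem_matrix", "word_regression", "pairwise_correlation_test",
    "group_features",
]


def survey_distance(a, b) -> float:
    """City-block (Manhattan) distance between two answer vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("answer vectors differ in length")
    return float(np.abs(a - b).sum())


def _answers(surveys: pd.DataFrame, subject) -> np.ndarray:
    """Concatenate one subject's answers across clips (sorted clip order)."""
    block = surveys.xs(subject, level="subject").sort_index()
    return block.to_numpy(dtype=float).reshape(-1)


def pair_distance_table(surveys_pre: pd.DataFrame,
                        surveys_post: pd.DataFrame,
                        group_labels: pd.Series) -> pd.DataFrame:
    """Long table of pairwise survey distances, one row per unordered
    pair per session, with before/within indicators."""
    subjects = list(surveys_pre.index.get_level_values("subject").unique())
    rows = []
    for si in range(len(subjects)):
        for sj in range(si):
            a, b = subjects[si], subjects[sj]
            ga, gb = group_labels[a], group_labels[b]
            within = int(ga == gb and ga != CONTROL_LABEL)
            for before, surveys in ((1, surveys_pre), (0, surveys_post)):
                d = survey_distance(_answers(surveys, a),
                                    _answers(surveys, b))
                rows.append({"pair": f"{a}|{b}", "subj_i": a, "subj_j": b,
                             "before": before, "within": within,
                             "distance": d})
    return pd.DataFrame(rows)


def _marginal_r2(result, data: pd.DataFrame, fixed: list) -> float:
    """Nakagawa-style marginal R2 for a random-intercept model:
    fixed-effect variance over fixed + random-intercept + residual."""
    fe = result.fe_params
    x = np.column_stack([np.ones(len(data))] +
                        [data[c].to_numpy(dtype=float) for c in fixed])
    pred = x @ fe.to_numpy()
    var_f = pred.var(ddof=0)
    var_r = float(np.squeeze(result.cov_re.to_numpy())) \
        if result.cov_re.size else 0.0
    var_e = float(result.scale)
    return var_f / (var_f + var_r + var_e)


def _fit_mixed(data: pd.DataFrame, dv: str, fixed: list, group: str):
    """Random-intercept mixed model; falls back to OLS if the variance
    structure is degenerate (e.g. zero residual variance)."""
    formula = f"{dv} ~ " + " + ".join(fixed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = smf.mixedlm(formula, data, groups=data[group]).fit(
                reml=True, method="lbfgs")
            if np.isfinite(res.fe_params).all():
                return res, _marginal_r2(res, data, fixed)
        except (np.linalg.LinAlgError, ValueError):
            pass
        ols = smf.ols(formula, data).fit()

    class _Shim:
        fe_params = ols.params
        pvalues = ols.pvalues
        cov_re = pd.DataFrame([[0.0]])
        scale = float(ols.mse_resid) if np.isfinite(ols.mse_resid) else 0.0
    return _Shim(), _marginal_r2(_Shim(), data, fixed)


def session_group_design(surveys_pre: pd.DataFrame,
                         surveys_post: pd.DataFrame,
                         group_labels: pd.Series,
                         n_perm: int = 200, seed: int = 0) -> dict:
    """Session x comparison-type model of pairwise survey distance.

    Builds the long pair-by-session table (both sessions required for
    every pair) and fits ``distance ~ before + within + before:within``
    with random intercepts per participant pair, delegated to a
    standard mixed-model routine.  The permutation p-value for marginal
    R2 shuffles the distance column across rows and refits.

    Returns a dict with ``coefficients`` (Series), ``marginal_r2``,
    ``p_marginal_r2`` and the long ``table``.
    """
    table = pair_distance_table(surveys_pre, surveys_post, group_labels)
    counts = table.groupby("pair")["before"].nunique()
    if (counts < 2).any():
        missing = counts.index[counts < 2].tolist()
        raise ValueError(f"pairs missing a session: {missing[:5]}")
    table = table.assign(before_within=table.before * table.within)
    fixed = ["before", "within", "before_within"]
    res, mr2 = _fit_mixed(table, "distance", fixed, "pair")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        shuffled = table.assign(
            distance=rng.permutation(table["distance"].to_numpy()))
        _, r2p = _fit_mixed(shuffled, "distance", fixed, "pair")
        exceed += r2p >= mr2
    return {
        "coefficients": res.fe_params,
        "marginal_r2": float(mr2),
        "p_marginal_r2": (1.0 + exceed) / (1.0 + n_perm),
        "table": table,
    }


def survey_influence(ego_pre, alter_pre, alter_post) -> float:
    """How far the alter's answers moved toward the ego's initial ones:
    ``d(ego_pre, alter_pre) - d(ego_pre, alter_post)`` (city-block).
    Positive values mean the alter converged toward the ego."""
    return survey_distance(ego_pre, alter_pre) \
        - survey_distance(ego_pre, alter_post)


def survey_influence_table(surveys_pre: pd.DataFrame,
                           surveys_post: pd.DataFrame,
                           group_labels: pd.Series | None = None,
                           same_group_only: bool = False) -> pd.DataFrame:
    """Survey influence for every ordered pair (ego, alter)."""
    subjects = list(surveys_pre.index.get_level_values("subject").unique())
    pre = {s: _answers(surveys_pre, s) for s in subjects}
    post = {s: _answers(surveys_post, s) for s in subjects}
    rows = []
    for e in subjects:
        for a in subjects:
            if e == a:
                continue
            if same_group_only:
                ge, ga = group_labels[e], group_labels[a]
                if ge != ga or ge == CONTROL_LABEL:
                    continue
            rows.append({"ego": e, "alter": a,
                         "influence": survey_influence(
                             pre[e], pre[a], post[a])})
    return pd.DataFrame(rows)


def gini(values) -> float:
    """Population Gini coefficient, no small-sample correction:
    ``G = sum_ij |x_i - x_j| / (2 n^2 mean(x))``."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if (x < 0).any():
        raise ValueError("negative values not allowed")
    if x.sum() == 0:
        raise ValueError("all-zero input: Gini undefined")
    xs = np.sort(x)
    n = x.size
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) @ xs) / (n * n * xs.mean()))


def word_stem_matrix(turns: pd.DataFrame, min_total: int = 5,
                     min_speakers: int = 10, min_clips: int = 3,
                     rare_token: str = "RAREWORD") -> pd.DataFrame:
    """Turn x stem count matrix with the study's filtering rules.

    ``turns`` must carry ``turn_id``, ``speaker``, ``clip`` and a
    whitespace-separated ``stems`` column (tokenization/stemming are
    upstream, pluggable preprocessing).  Filters, in order: stems used
    fewer than ``min_total`` times across all conversations are folded
    into the ``rare_token`` column; remaining stems are kept only if
    used by at least ``min_speakers`` distinct speakers and in at least
    ``min_clips`` distinct clips.  Stems failing the breadth filters
    are dropped (not folded).  The filters are idempotent.
    """
    if turns.empty:
        raise ValueError("empty corpus")
    long = (turns.assign(stem=turns["stems"].str.split())
            .explode("stem").dropna(subset=["stem"]))
    long = long[long["stem"] != ""]
    if long.empty:
        raise ValueError("no stems present in corpus")
    totals = long.groupby("stem").size()
    rare = set(totals.index[totals < min_total]) - {rare_token}
    long = long.assign(stem=long["stem"].where(
        ~long["stem"].isin(rare), rare_token))
    breadth = long[long["stem"] != rare_token].groupby("stem").agg(
        speakers=("speaker", "nunique"), clips=("clip", "nunique"))
    keep = set(breadth.index[(breadth["speakers"] >= min_speakers)
                             & (breadth["clips"] >= min_clips)])
    long = long[long["stem"].isin(keep | {rare_token})]
    mat = (long.groupby(["turn_id", "stem"]).size()
           .unstack(fill_value=0))
    mat = mat.reindex(turns["turn_id"], fill_value=0)
    mat.columns.name = None
    ordered = sorted(c for c in mat.columns if c != rare_token)
    if rare_token in mat.columns:
        ordered.append(rare_token)
    return mat[ordered]


def word_regression(matrix: pd.DataFrame, covariate: pd.Series,
                    speakers: pd.Series, n_perm: int = 0,
                    seed: int = 0) -> pd.DataFrame:
    """OLS of a z-scored speaker covariate on word-stem counts.

    One multiple regression: target = covariate per turn (constant
    within speaker), predictors = stem counts plus an intercept.  Betas
    read as predicted standard deviations from the cohort mean per unit
    count.  Collinear stems are dropped and flagged.  Optional
    permutation p-values shuffle the covariate across *speakers*
    (covariates are constant within speaker, so turn-level shuffling
    would break exchangeability).
    """
    y = covariate.loc[matrix.index].to_numpy(dtype=float)
    x = matrix.to_numpy(dtype=float)
    names = list(matrix.columns)
    keep, dropped = [], []
    xcols = [np.ones(len(matrix))]
    for k, name in enumerate(names):
        trial = np.column_stack(xcols + [x[:, k]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            xcols.append(x[:, k])
            keep.append(name)
        else:
            dropped.append(name)
    xmat = np.column_stack(xcols)
    beta, *_ = np.linalg.lstsq(xmat, y, rcond=None)
    out = pd.DataFrame({"beta": beta[1:]}, index=pd.Index(keep, name="stem"))
    out["dropped_collinear"] = False
    for name in dropped:
        out.loc[name] = [np.nan, True]
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        spk = speakers.loc[matrix.index]
        uniq = spk.unique()
        per_spk = pd.Series(
            {s: covariate.loc[matrix.index][spk == s].iloc[0]
             for s in uniq})
        pinv = np.linalg.pinv(xmat)
        obs = beta[1:]
        exceed = np.zeros_like(obs)
        for _ in range(n_perm):
            shuffled = pd.Series(rng.permutation(per_spk.to_numpy()),
                                 index=uniq)
            yp = spk.map(shuffled).to_numpy(dtype=float)
            bp = (pinv @ yp)[1:]
            exceed += np.abs(bp) >= np.abs(obs)
        pvals = (1.0 + exceed) / (1.0 + n_perm)
        out["p_perm"] = np.nan
        out.loc[keep, "p_perm"] = pvals
    return out


def pairwise_correlation_test(x: pd.Series, y: pd.Series,
                              pair_index: pd.DataFrame,
                              subject_ids, n_perm: int = 2000,
                              seed: int = 0,
                              ordered: bool = False) -> dict:
    """Pearson r over pair-structured data with a subject-wise
    permutation p-value.

    ``x`` and ``y`` are aligned per-pair values; ``pair_index`` has
    columns (i, j) giving each row's subject positions.  The null
    relabels subjects and re-reads ``y`` at the relabeled cells, which
    respects the non-independence of pairs sharing a subject.
    """
    if len(x) != len(y) or len(x) != len(pair_index):
        raise ValueError("x, y and pair_index must align")
    n = len(subject_ids)
    ii = pair_index["i"].to_numpy()
    jj = pair_index["j"].to_numpy()
    ymat = np.full((n, n), np.nan)
    ymat[ii, jj] = y.to_numpy(dtype=float)
    if not ordered:
        ymat[jj, ii] = y.to_numpy(dtype=float)
    xv = x.to_numpy(dtype=float)
    r_obs = float(np.corrcoef(xv, y.to_numpy(dtype=float))[0, 1])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = ymat[perm[ii], perm[jj]]
        ok = ~np.isnan(yp)
        r = np.corrcoef(xv[ok], yp[ok])[0, 1]
        exceed += abs(r) >= abs(r_obs)
    return {"r": r_obs, "p_two_tailed": (1.0 + exceed) / (1.0 + n_perm),
            "n_pairs": len(x)}


def group_features(turns: pd.DataFrame,
                   centrality: pd.Series | None = None,
                   status: pd.Series | None = None) -> pd.DataFrame:
    """Per group x clip conversation features: total words and Gini
    inequality of words spoken (optionally of centrality / perceived
    status over the group's members)."""
    rows = []
    for (grp, clip), sub in turns.groupby(["group", "clip"]):
        words = sub.groupby("speaker")["n_words"].sum()
        row = {"group": grp, "clip": clip,
               "total_words": int(words.sum()),
               "gini_words": gini(words.to_numpy())}
        members = words.index
        if centrality is not None:
            c = centrality.loc[members].to_numpy(dtype=float)
            row["gini_centrality"] = gini(c - c.min() + 1e-9) \
                if len(c) else np.nan
        if status is not None:
            s = status.loc[members].to_numpy(dtype=float)
            row["gini_status"] = gini(s - s.min() + 1e-9)
        rows.append(row)
    return pd.DataFrame(rows)
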