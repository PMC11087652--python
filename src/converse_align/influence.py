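"""Directed ego -> alter neural influence and its centrality regression.

Influence asks how far the alter moved toward the ego's *initial*
activity: per voxel and ordered pair (ego e, alter a),

    influence(e, a) = ISC(e_pre, a_post) - ISC(e_pre, a_pre)

i.e. the initial-position matrix subtracted from the final-position
matrix.  Positive values mean the alter's after-conversation series
became more similar to the ego's before-conversation series.  Unlike
the change analysis, both triangles are used (every subject appears as
ego and as alter); the diagonal is undefined.

Centrality regressions replace the 1s of the group predictors with the
ego's or the alter's z-scored social-network centrality; only ordered
pairs within the same conversation group enter, and the two composite
models of interest are PCA centrality alone, or eigenvector centrality
and brokerage jointly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .change import PairwiseDesign, RegressionMaps, fit_pairwise_regression
from .isc import IscStack, cross_isc_matrix, isc_matrix, BoldSession

__all__ = [
    "InfluenceStack", "influence_stack", "influence_from_sessions",
    "build_centrality_design", "fit_influence_regression",
    "whole_brain_influence",
]


class InfluenceStack(IscStack):
    """(voxels, N, N) influence values; entry (v, e, a) is ego e ->
    alter a.  Not symmetric; diagonal NaN; values in [-2, 2]."""


def influence_stack(pre: IscStack, final: IscStack) -> InfluenceStack:
    """Final-position minus initial-position matrices.

    ``pre`` is the within-session before-conversation ISC (initial
    position); ``final`` is the cross-session stack whose (e, a) entry
    correlates ego e's pre series with alter a's post series.
    """
    if list(pre.subject_ids) != list(final.subject_ids):
        raise ValueError("subject mismatch between stacks")
    if pre.values.shape != final.values.shape:
        raise ValueError("shape mismatch between stacks")
    vals = final.values - pre.values
    n = len(pre.subject_ids)
    vals[:, np.arange(n), np.arange(n)] = np.nan
    return InfluenceStack(values=vals, subject_ids=list(pre.subject_ids),
                          group_labels=list(pre.group_labels),
                          clip_id=pre.clip_id, symmetric=False,
                          grid_shape=pre.grid_shape)


def influence_from_sessions(bold_pre: BoldSession,
                            bold_post: BoldSession) -> InfluenceStack:
    """Convenience: compute both position matrices from raw sessions."""
    return influence_stack(isc_matrix(bold_pre),
                           cross_isc_matrix(bold_pre, bold_post))


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=0)
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def build_centrality_design(group_labels, clips, centrality,
                            subject_ids, metrics=("pca",),
                            control_label: str = "control",
                            zscore: bool = True) -> PairwiseDesign:
    """Ego/alter centrality predictors over ordered same-group pairs.

    ``centrality`` is a DataFrame indexed by subject id with one column
    per metric (e.g. ``pca``, ``eigenvector``, ``brokerage``).  Rows
    enumerate ordered pairs (e, a), e != a, both members in the same
    conversation group (controls excluded), both triangles, in
    (clip, ego-major, alter-minor) order.  Each metric contributes an
    ``ego:<metric>`` and an ``alter:<metric>`` column holding that
    member's centrality, z-scored over the included study participants
    by default; an all-1s intercept is included.
    """
    group_labels = list(group_labels)
    subject_ids = list(subject_ids)
    n = len(group_labels)
    lab = np.array(group_labels)
    ee, aa = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    keep = (ee != aa) & (lab[ee] == lab[aa]) & (lab[ee] != control_label)
    ee, aa = ee[keep], aa[keep]
    if len(ee) == 0:
        raise ValueError("no same-group ordered pairs")
    cent = centrality.loc[subject_ids]
    cols = {}
    for m in metrics:
        v = cent[m].to_numpy(dtype=float)
        participants = sorted(set(ee) | set(aa))
        if zscore:
            z = np.full(n, np.nan)
            z[participants] = _zscore(v[participants])
        else:
            z = v
        cols[f"ego:{m}"] = z[ee]
        cols[f"alter:{m}"] = z[aa]
    names = ["intercept"] + list(cols)
    rows_per_clip = len(ee)
    block = np.column_stack(
        [np.ones(rows_per_clip)] + [cols[c] for c in cols])
    mat = np.tile(block, (len(clips), 1))
    pair_index = pd.DataFrame({
        "clip": np.repeat(list(clips), rows_per_clip),
        "i": np.tile(ee, len(clips)),
        "j": np.tile(aa, len(clips)),
    })
    return PairwiseDesign(matrix=mat, names=names, pair_index=pair_index,
                          subject_ids=subject_ids, ordered=True)


def fit_influence_regression(influence, design: PairwiseDesign
                             ) -> RegressionMaps:
    """Per-voxel OLS of vectorized influence on centrality predictors."""
    return fit_pairwise_regression(influence, design,
                                   model_tag="influence")


def whole_brain_influence(stacks) -> pd.DataFrame:
    """Sum of positive influence over voxels, per ordered pair.

    ``stacks`` is one InfluenceStack or a list (one per clip).  Returns
    a long DataFrame (clip, ego, alter, influence) over ordered pairs,
    diagonal excluded; NaN voxels ignored.
    """
    if not isinstance(stacks, (list, tuple)):
        stacks = [stacks]
    rows = []
    for st in stacks:
        ids = list(st.subject_ids)
        n = len(ids)
        pos = np.nansum(np.clip(st.values, 0.0, None), axis=0)
        ee, aa = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        keep = ee != aa
        rows.append(pd.DataFrame({
            "clip": st.clip_id,
            "ego": [ids[e] for e in ee[keep]],
            "alter": [ids[a] for a in aa[keep]],
            "influence": pos[ee[keep], aa[keep]]}))
    return pd.concat(rows, ignore_index=True)
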