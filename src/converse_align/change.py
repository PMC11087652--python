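"""Conversation-induced change in ISC: pair-matrix regression with
subject-wise permutation inference and cluster-extent correction.

The target is the voxel-wise *change matrix* (after-conversation ISC
minus before-conversation ISC).  Predictor matrices over participant
pairs are vectorized — only the strict lower triangle of each symmetric
matrix is used — and concatenated across clips, then fit per voxel by
ordinary least squares.  A group column is 1 where both pair members
belong to that group; the all-1s intercept absorbs change that occurs
regardless of conversation (e.g. from watching a clip twice), so
control-group and between-group pairs always stay in the rows.

Inference is by subject-wise permutation: one subject relabeling per
draw, applied identically to the rows and columns of every clip's
target matrix (the same relabeling across clips, preserving subject
exchangeability in the concatenated model) while the design is held
fixed.  Two-tailed p-values use add-one smoothing
``p = (1 + #{|b_perm| >= |b_obs|}) / (1 + n_perm)`` by default; the
raw-proportion rule is available behind ``smoothing=False``.

Cluster correction retains connected components of suprathreshold
voxels (per predictor, per sign) of at least ``min_size`` voxels, or —
when a permutation max-cluster null is supplied — larger than its 95th
percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import ndimage

from .isc import IscStack

__all__ = [
    "ChangeStack", "PairwiseDesign", "RegressionMaps", "PermutationResult",
    "change_stack", "build_design", "fit_pairwise_regression",
    "novel_clip_regression", "subjectwise_permutation", "max_cluster_null",
    "cluster_correct", "whole_brain_alignment", "vectorize_stacks",
]


@dataclass
class ChangeStack:
    """Per-voxel post-minus-pre ISC change matrices ``(voxels, N, N)``."""

    values: np.ndarray
    subject_ids: list
    group_labels: list = field(default_factory=list)
    clip_id: str = "clip0"
    grid_shape: tuple | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or \
                self.values.shape[1] != self.values.shape[2]:
            raise ValueError("values must be (voxels, N, N)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]


@dataclass
class PairwiseDesign:
    """Vectorized predictor columns over pairs, concatenated across clips.

    ``matrix`` is (rows x predictors); ``pair_index`` is a DataFrame
    with columns (clip, i, j) giving, per row, the clip and the
    subject *positions* (row/column indices into the pair matrices)
    that the row reads.  For the unordered change analysis ``i > j``
    (strict lower triangle); the influence analysis uses both
    triangles (``ordered=True``).
    """

    matrix: np.ndarray
    names: list
    pair_index: pd.DataFrame
    subject_ids: list
    ordered: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.pair_index):
            raise ValueError("design rows != pair_index rows")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("design columns != names")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]


@dataclass
class RegressionMaps:
    """Per-voxel OLS coefficients (voxels x predictors)."""

    betas: np.ndarray
    names: list
    model_tag: str = "change"
    grid_shape: tuple | None = None


@dataclass
class PermutationResult:
    """Two-tailed permutation p-values (voxels x predictors)."""

    p_two_tailed: np.ndarray
    names: list
    n_permutations: int
    seed: int | None
    null_betas: np.ndarray | None = None   # (n_perm, voxels, predictors)


def change_stack(pre: IscStack, post: IscStack) -> ChangeStack:
    """Element-wise post - pre; NaN where either input is undefined."""
    if list(pre.subject_ids) != list(post.subject_ids):
        raise ValueError("pre/post subject mismatch")
    if pre.values.shape != post.values.shape:
        raise ValueError("pre/post shape mismatch")
    if pre.clip_id != post.clip_id:
        raise ValueError(f"clip mismatch: {pre.clip_id} vs {post.clip_id}")
    return ChangeStack(values=post.values - pre.values,
                       subject_ids=list(pre.subject_ids),
                       group_labels=list(pre.group_labels),
                       clip_id=pre.clip_id,
                       grid_shape=pre.grid_shape or post.grid_shape)


def _group_columns(group_labels, mode: str, control_label: str):
    groups = []
    for l in group_labels:
        if l != control_label and l not in groups:
            groups.append(l)
    counts = {g: group_labels.count(g) for g in groups}
    small = [g for g in groups if counts[g] < 2]
    if small:
        raise ValueError(
            f"groups with < 2 members would give all-zero columns: {small}")
    if mode == "per_group":
        return groups
    if mode == "all_groups":
        return ["any_group"]
    raise ValueError(f"unknown design mode: {mode!r}")


def build_design(group_labels, clips, mode: str = "per_group",
                 subject_ids=None,
                 control_label: str = "control") -> PairwiseDesign:
    """Intercept + group-membership predictors over all unordered pairs.

    Rows enumerate the strict lower triangle (i > j) of the N x N pair
    matrix for each clip in ``clips``, in clip order; all pairs —
    between-group and control pairs included — contribute rows.  In
    ``per_group`` mode there is one indicator column per conversation
    group (1 iff both members are in that group); in ``all_groups`` mode
    a single ``any_group`` column marks same-group pairs of any group.
    The reserved ``control_label`` never forms a column.
    """
    group_labels = list(group_labels)
    n = len(group_labels)
    if subject_ids is None:
        subject_ids = list(range(n))
    cols = _group_columns(group_labels, mode, control_label)
    ii, jj = np.tril_indices(n, k=-1)
    rows_per_clip = len(ii)
    names = ["intercept"] + [f"group:{g}" if mode == "per_group" else g
                             for g in cols]
    block = np.zeros((rows_per_clip, len(names)))
    block[:, 0] = 1.0
    lab = np.array(group_labels)
    for k, g in enumerate(cols, start=1):
        if mode == "per_group":
            block[:, k] = (lab[ii] == g) & (lab[jj] == g)
        else:
            block[:, k] = (lab[ii] == lab[jj]) & (lab[ii] != control_label)
    mat = np.tile(block, (len(clips), 1))
    pair_index = pd.DataFrame({
        "clip": np.repeat(list(clips), rows_per_clip),
        "i": np.tile(ii, len(clips)),
        "j": np.tile(jj, len(clips)),
    })
    return PairwiseDesign(matrix=mat, names=names, pair_index=pair_index,
                          subject_ids=list(subject_ids), ordered=False)


def vectorize_stacks(stacks, design: PairwiseDesign,
                     perm: np.ndarray | None = None) -> np.ndarray:
    """Unravel pair matrices into the (rows x voxels) target.

    ``stacks`` maps clip id -> (voxels, N, N) array (or is a list of
    ChangeStack/IscStack in design clip order).  If ``perm`` is given,
    rows and columns of every clip's matrix are identically relabeled
    (subject-wise permutation) before reading the design's cells.
    """
    if not isinstance(stacks, dict):
        stacks = {s.clip_id: s for s in stacks}
    out = []
    for clip, sub in design.pair_index.groupby("clip", sort=False):
        s = stacks[clip]
        vals = s.values if hasattr(s, "values") else np.asarray(s)
        i = sub["i"].to_numpy()
        j = sub["j"].to_numpy()
        if perm is not None:
            i, j = perm[i], perm[j]
        out.append(vals[:, i, j].T)     # rows x voxels
    return np.concatenate(out, axis=0)


def _check_rank(x: np.ndarray, names):
    if np.linalg.matrix_rank(x) < x.shape[1]:
        _, r = np.linalg.qr(x)
        bad = [names[k] for k in range(x.shape[1])
               if abs(r[k, k]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"design is rank deficient; collinear columns: "
                         f"{bad or names}")


def _ols_betas(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-voxel OLS with NaN target rows dropped per voxel.

    ``y`` is (rows x voxels); returns (voxels x predictors).
    """
    nan_mask = np.isnan(y)
    if not nan_mask.any():
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        return beta.T
    betas = np.full((y.shape[1], x.shape[1]), np.nan)
    for v in range(y.shape[1]):
        keep = ~nan_mask[:, v]
        if keep.sum() <= x.shape[1]:
            continue
        b, *_ = np.linalg.lstsq(x[keep], y[keep, v], rcond=None)
        betas[v] = b
    return betas


def fit_pairwise_regression(target, design: PairwiseDesign,
                            model_tag: str = "change") -> RegressionMaps:
    """Per-voxel OLS of the vectorized target on the pair design.

    ``target`` may be a list/dict of stacks (vectorized here) or an
    already-vectorized (rows x voxels) array whose rows match the
    design.  Undefined (NaN) target rows are dropped per voxel.
    """
    if isinstance(target, np.ndarray) and target.ndim == 2:
        y = target
        grid = None
    else:
        y = vectorize_stacks(target, design)
        seq = list(target.values()) if isinstance(target, dict) else target
        grid = getattr(seq[0], "grid_shape", None)
    if y.shape[0] != design.n_rows:
        raise ValueError("target rows do not match design rows")
    _check_rank(design.matrix, design.names)
    betas = _ols_betas(design.matrix, y)
    return RegressionMaps(betas=betas, names=list(design.names),
                          model_tag=model_tag, grid_shape=grid)


def novel_clip_regression(post, design: PairwiseDesign) -> RegressionMaps:
    """Same model but with the after-conversation ISC itself as target
    (used for novel clips never discussed), tagged ``novel_post``."""
    return fit_pairwise_regression(post, design, model_tag="novel_post")


def _perm_draws(n_subjects: int, n_perm: int, rng, exhaustive: bool):
    if exhaustive:
        return [np.array(p) for p in permutations(range(n_subjects))]
    return [rng.permutation(n_subjects) for _ in range(n_perm)]


def subjectwise_permutation(target, design: PairwiseDesign,
                            n_perm: int = 2000, seed: int = 0,
                            smoothing: bool = True,
                            exhaustive: bool = False,
                            keep_null: bool = False) -> PermutationResult:
    """Subject-wise permutation p-values for every design coefficient.

    For each draw one subject relabeling is applied identically to the
    rows and columns of every clip's target matrix (the same relabeling
    across clips); the design stays fixed; betas are recomputed.  The
    two-tailed p is the add-one-smoothed proportion of permuted
    ``|beta|`` at least as extreme as the observed one (raw proportion
    with ``smoothing=False``).  ``exhaustive=True`` enumerates all N!
    relabelings (small N only) and ignores ``n_perm``/``seed``.
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    if not isinstance(target, dict):
        target = {s.clip_id: s for s in target}
    _check_rank(design.matrix, design.names)
    y_obs = vectorize_stacks(target, design)
    obs = _ols_betas(design.matrix, y_obs)          # voxels x preds
    n = len(design.subject_ids)
    rng = np.random.default_rng(seed)
    draws = _perm_draws(n, n_perm, rng, exhaustive)

    clean = not any(np.isnan(s.values if hasattr(s, "values") else s).any()
                    for s in target.values())
    if clean:
        x = design.matrix
        pinv = np.linalg.pinv(x)                    # preds x rows
    exceed = np.zeros_like(obs)
    null = np.empty((len(draws), *obs.shape)) if keep_null else None
    for k, perm in enumerate(draws):
        y = vectorize_stacks(target, design, perm=perm)
        b = (pinv @ y).T if clean else _ols_betas(design.matrix, y)
        exceed += np.abs(b) >= np.abs(obs)
        if keep_null:
            null[k] = b
    m = len(draws)
    if exhaustive:
        # the identity is among the enumerated relabelings, so the raw
        # proportion is already bounded away from zero
        p = exceed / m
    elif smoothing:
        p = (1.0 + exceed) / (1.0 + m)
    else:
        p = exceed / m
    return PermutationResult(p_two_tailed=p, names=list(design.names),
                             n_permutations=m,
                             seed=None if exhaustive else seed,
                             null_betas=null)


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)


def max_cluster_null(perm_result: PermutationResult, grid_shape,
                     predictor: str, cluster_forming_p: float = 0.01,
                     connectivity: int = 6) -> np.ndarray:
    """Max suprathreshold cluster size under each permutation draw.

    Requires ``subjectwise_permutation(..., keep_null=True)``.  Each
    permuted beta map is converted to voxelwise pseudo-p values against
    the pooled null at its own voxel, thresholded and labeled exactly
    like the observed map, and the largest component size recorded.
    """
    if perm_result.null_betas is None:
        raise ValueError("permutation result lacks null betas "
                         "(run with keep_null=True)")
    k = perm_result.names.index(predictor)
    null = perm_result.null_betas[:, :, k]          # n_perm x voxels
    m = null.shape[0]
    ranks = np.argsort(np.argsort(np.abs(null), axis=0), axis=0)
    pnull = (m - ranks) / m                         # fraction >= self
    struct = _structure(connectivity)
    out = np.empty(m, dtype=int)
    for q in range(m):
        mask = (pnull[q] < cluster_forming_p).reshape(grid_shape)
        lab, nlab = ndimage.label(mask, structure=struct)
        out[q] = 0 if nlab == 0 else int(
            np.max(ndimage.sum_labels(np.ones_like(lab), lab,
                                      range(1, nlab + 1))))
    return out


def cluster_correct(maps: RegressionMaps, perm: PermutationResult,
                    grid_shape=None, cluster_forming_p: float = 0.01,
                    min_size: int = 32, connectivity: int = 6,
                    null_max_sizes: np.ndarray | None = None,
                    n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Cluster-extent corrected table of suprathreshold components.

    Per predictor and per sign (positive/negative betas corrected
    separately), voxels with ``p < cluster_forming_p`` are grouped into
    connected components on the 3-D grid (face adjacency by default).
    A component survives if its size is at least ``min_size``, or, when
    ``null_max_sizes`` is given, strictly exceeds the null's 95th
    percentile.  Reports mean, peak and bootstrap 95% CI of member
    betas plus member voxel indices.
    """
    grid_shape = grid_shape or maps.grid_shape
    if grid_shape is None:
        raise ValueError("3-D grid geometry required for clustering")
    grid_shape = tuple(grid_shape)
    if int(np.prod(grid_shape)) != maps.betas.shape[0]:
        raise ValueError("grid_shape does not match number of voxels")
    struct = _structure(connectivity)
    rng = np.random.default_rng(seed)
    thresh = (None if null_max_sizes is None
              else float(np.percentile(null_max_sizes, 95)))
    rows = []
    for k, name in enumerate(maps.names):
        pv = perm.p_two_tailed[:, maps.names.index(name)]
        for sign, signname in ((1, "positive"), (-1, "negative")):
            mask = (pv < cluster_forming_p) & \
                (np.sign(maps.betas[:, k]) == sign)
            lab, nlab = ndimage.label(mask.reshape(grid_shape),
                                      structure=struct)
            lab = lab.reshape(-1)
            for c in range(1, nlab + 1):
                vox = np.nonzero(lab == c)[0]
                size = len(vox)
                if thresh is not None:
                    if size <= thresh:
                        continue
                elif size < min_size:
                    continue
                b = maps.betas[vox, k]
                boot = rng.choice(b, size=(n_boot, size)).mean(axis=1)
                lo, hi = np.percentile(boot, [2.5, 97.5])
                peak = b[np.argmax(np.abs(b))]
                rows.append({
                    "predictor": name, "sign": signname,
                    "n_voxels": size,
                    "voxel_indices": ",".join(map(str, vox)),
                    "beta_mean": float(b.mean()),
                    "beta_peak": float(peak),
                    "beta_ci_low": float(lo), "beta_ci_high": float(hi)})
    return pd.DataFrame(rows, columns=[
        "predictor", "sign", "n_voxels", "voxel_indices", "beta_mean",
        "beta_peak", "beta_ci_low", "beta_ci_high"])


def whole_brain_alignment(changes) -> pd.DataFrame:
    """Sum of unthresholded positive ISC change over voxels, per pair.

    ``changes`` is one ChangeStack or a list of them (summed over
    clips).  Returns a long DataFrame (subj_i, subj_j, alignment) over
    unordered pairs; NaN voxels are ignored.
    """
    if not isinstance(changes, (list, tuple)):
        changes = [changes]
    ids = list(changes[0].subject_ids)
    n = len(ids)
    total = np.zeros((n, n))
    for ch in changes:
        if list(ch.subject_ids) != ids:
            raise ValueError("subject mismatch across change stacks")
        total += np.nansum(np.clip(ch.values, 0.0, None), axis=0)
    ii, jj = np.tril_indices(n, k=-1)
    return pd.DataFrame({
        "subj_i": [ids[i] for i in ii],
        "subj_j": [ids[j] for j in jj],
        "alignment": total[ii, jj]})
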