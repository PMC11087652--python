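"""Inter-subject correlation (ISC) of voxel time series.

ISC is the Pearson correlation of two subjects' BOLD time series at the
same voxel.  No Fisher z-transform is applied anywhere by default: the
change analysis subtracts raw correlation values, so r is kept on its
native scale (``fisher_z=True`` is available for sensitivity analyses
only).  Voxels with zero temporal variance in a subject yield NaN (an
explicit undefined marker, not 0) and are dropped from downstream
regressions and summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoldSession", "IscStack", "pairwise_isc", "isc_matrix",
    "cross_isc_matrix", "windowed_group_isc",
]


@dataclass
class BoldSession:
    """One session/clip of BOLD data: ``(subjects, voxels, timepoints)``.

    ``grid_shape`` is the 3-D voxel grid the flat voxel axis unravels to
    (row-major); it is metadata required only by cluster-level analyses.
    """

    data: np.ndarray
    subject_ids: list
    group_labels: list
    clip_id: str = "clip0"
    tr_seconds: float = 1.0
    grid_shape: tuple | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (subjects, voxels, timepoints)")
        n, v, t = self.data.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match data")
        if len(self.group_labels) != n:
            raise ValueError("group_labels length does not match data")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject ids must be unique")
        if t < 2:
            raise ValueError("need at least 2 timepoints")
        if self.grid_shape is not None:
            self.grid_shape = tuple(int(s) for s in self.grid_shape)
            if int(np.prod(self.grid_shape)) != v:
                raise ValueError(
                    f"grid_shape {self.grid_shape} does not flatten to "
                    f"{v} voxels")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    def reorder(self, order: np.ndarray) -> "BoldSession":
        """Return a copy with subjects permuted by ``order``."""
        order = np.asarray(order)
        return BoldSession(
            data=self.data[order],
            subject_ids=[self.subject_ids[i] for i in order],
            group_labels=[self.group_labels[i] for i in order],
            clip_id=self.clip_id, tr_seconds=self.tr_seconds,
            grid_shape=self.grid_shape)


@dataclass
class IscStack:
    """Per-voxel pairwise correlation matrices: ``(voxels, N, N)``.

    Symmetric in the last two axes for within-session ISC; the diagonal
    is 1 where defined.  ``cross_isc_matrix`` produces a non-symmetric
    variant (row subject from one session, column subject from another)
    used by the influence analysis, flagged by ``symmetric=False``.
    """

    values: np.ndarray
    subject_ids: list
    group_labels: list = field(default_factory=list)
    session_tag: str = "pre"
    clip_id: str = "clip0"
    symmetric: bool = True
    grid_shape: tuple | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or \
                self.values.shape[1] != self.values.shape[2]:
            raise ValueError("values must be (voxels, N, N)")
        if self.values.shape[1] != len(self.subject_ids):
            raise ValueError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


def pairwise_isc(a, b) -> float:
    """Pearson correlation of two equal-length time series.

    Returns NaN if either series has zero variance (undefined marker).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series lengths differ")
    if a.ndim != 1 or a.size < 2:
        raise ValueError("series must be 1-D with length >= 2")
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.sqrt(ac @ ac)
    nb = np.sqrt(bc @ bc)
    if na == 0.0 or nb == 0.0:
        return float("nan")
    return float(np.clip((ac @ bc) / (na * nb), -1.0, 1.0))


def _unit_rows(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demean along time and scale to unit norm; flag zero-variance rows."""
    x = data - data.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(x, axis=-1)
    bad = norm == 0.0
    safe = np.where(bad, 1.0, norm)
    return x / safe[..., None], bad


def isc_matrix(session: BoldSession, fisher_z: bool = False) -> IscStack:
    """Voxel-wise N x N pairwise ISC matrices for one session.

    Equivalent to calling :func:`pairwise_isc` on every subject pair at
    every voxel, but vectorized.  Entries touching a zero-variance
    series are NaN; defined diagonal entries are exactly 1.
    """
    if session.n_subjects < 2:
        raise ValueError("ISC requires at least 2 subjects")
    xn, bad = _unit_rows(session.data)          # (N, V, T), (N, V)
    vals = np.einsum("ivt,jvt->vij", xn, xn)
    vals = np.clip(vals, -1.0, 1.0)
    n = session.n_subjects
    vals[:, np.arange(n), np.arange(n)] = 1.0
    if bad.any():
        bv, bs = np.nonzero(bad.T)              # voxel, subject
        vals[bv, bs, :] = np.nan
        vals[bv, :, bs] = np.nan
    if fisher_z:
        vals = np.arctanh(np.clip(vals, -1 + 1e-12, 1 - 1e-12))
    return IscStack(values=vals, subject_ids=list(session.subject_ids),
                    group_labels=list(session.group_labels),
                    clip_id=session.clip_id, grid_shape=session.grid_shape)


def cross_isc_matrix(row_session: BoldSession, col_session: BoldSession,
                     fisher_z: bool = False) -> IscStack:
    """ISC between two sessions: entry ``(v, i, j)`` correlates subject
    ``i``'s series in ``row_session`` with subject ``j``'s series in
    ``col_session`` at voxel ``v``.  Not symmetric.
    """
    if list(row_session.subject_ids) != list(col_session.subject_ids):
        raise ValueError("sessions must contain the same subjects in "
                         "the same order")
    if row_session.data.shape[1] != col_session.data.shape[1]:
        raise ValueError("voxel count mismatch between sessions")
    xr, badr = _unit_rows(row_session.data)
    xc, badc = _unit_rows(col_session.data)
    vals = np.einsum("ivt,jvt->vij", xr, xc)
    vals = np.clip(vals, -1.0, 1.0)
    if badr.any():
        bv, bs = np.nonzero(badr.T)
        vals[bv, bs, :] = np.nan
    if badc.any():
        bv, bs = np.nonzero(badc.T)
        vals[bv, :, bs] = np.nan
    if fisher_z:
        vals = np.arctanh(np.clip(vals, -1 + 1e-12, 1 - 1e-12))
    return IscStack(values=vals, subject_ids=list(row_session.subject_ids),
                    group_labels=list(row_session.group_labels),
                    clip_id=row_session.clip_id, symmetric=False,
                    grid_shape=row_session.grid_shape)


def windowed_group_isc(session: BoldSession, pair_set, window: int = 10,
                       step: int = 1, voxels=None):
    """Rolling-window mean pairwise ISC over a set of subject pairs.

    The window spans ``window`` TRs and advances by ``step`` TRs; each
    window's mean pairwise ISC (averaged over ``pair_set`` and over the
    selected voxels) is mapped to the TR at the window's center (index
    ``start + window // 2``; leftward tie-break for even windows).

    Returns ``(centers, values)`` arrays.  At step 1 there are
    ``T - window + 1`` points.
    """
    if window < 3:
        raise ValueError("window must be >= 3 (correlation degenerate)")
    if step < 1:
        raise ValueError("step must be >= 1")
    t = session.n_timepoints
    if t < window:
        raise ValueError("timepoints < window")
    pair_set = [(int(i), int(j)) for i, j in pair_set]
    if not pair_set:
        raise ValueError("pair_set is empty")
    data = session.data if voxels is None else session.data[:, voxels, :]
    starts = np.arange(0, t - window + 1, step)
    centers = starts + window // 2
    out = np.empty(len(starts))
    for k, s in enumerate(starts):
        chunk = data[:, :, s:s + window]
        xn, bad = _unit_rows(chunk)
        rs = []
        for i, j in pair_set:
            r = np.einsum("vt,vt->v", xn[i], xn[j])
            r[bad[i] | bad[j]] = np.nan
            rs.append(r)
        out[k] = np.nanmean(np.concatenate(rs))
    return centers, out
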