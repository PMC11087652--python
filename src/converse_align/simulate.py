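"""Synthetic cohorts with the statistical structure the analyses assume.

The generator emulates a consensus-conversation study: N subjects in G
conversation groups (plus a no-conversation control group) are "scanned"
twice while viewing the same clips.  Each subject's voxel time series is
a variance-partitioned mixture of independent unit-variance sources::

    x[s, v, t] = sqrt(a) * g[v, t]                       cohort-wide signal
               + sqrt(b_session) * h[group(s), v, t]     group signal
               + sqrt(1 - a - b_session) * eps[s, v, t]  subject noise

so every series has unit variance and the expected pairwise ISC has a
closed form: ``a + b`` within a group at an affected voxel, ``a``
otherwise.  The stimulus-driven components g and h belong to the clip
and are shared across the two viewings (only the noise is redrawn), so
the expected cross-session ISC is ``a + sqrt(b_pre * b_post)`` within a
group at an affected voxel and the ego -> alter influence statistic is
centred on zero in the absence of injected imitation.  Raising ``b`` from the pre to the post session plants a
group-convergence effect of known size ``b_post - b_pre``; the affected
voxels form a contiguous 3-D block so cluster-level inference has
spatial structure to find.

Directed imitation is injected per ordered pair: the alter's post
series becomes ``sqrt(w) * ego_pre + sqrt(1 - w) * noise``, giving
``ISC(ego_pre, alter_post) = sqrt(w)`` in expectation.

Everything is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .isc import BoldSession

__all__ = [
    "SimulationConfig", "SyntheticCohort", "generate_bold",
    "inject_influence", "generate_network", "generate_surveys",
    "generate_turns", "generate_cohort", "CONTROL_LABEL",
]

#: Reserved group label for no-conversation controls; never forms a
#: predictor column.
CONTROL_LABEL = "control"


@dataclass
class SimulationConfig:
    """Cohort-generator parameters.

    Defaults emulate the study design this package targets: 9
    conversation groups of 3-6 members (40 conversers) plus 9 controls,
    5 clips, two sessions.  The voxel grid is a desk-scale stand-in for
    a whole brain; ``affected_block`` is the contiguous sub-block of
    voxels that carries the group-convergence signal.

    Variance fractions: ``a_shared`` (cohort-wide stimulus signal),
    ``b_group_pre`` / ``b_group_post`` (group signal before/after
    conversation), ``influence_weight`` (per-ordered-pair imitation,
    applied only via :func:`inject_influence`).  They must satisfy
    ``a_shared + max(b_group_pre, b_group_post) + influence_weight < 1``.
    """

    group_sizes: tuple = (4, 4, 4, 4, 4, 4, 5, 5, 6)
    n_controls: int = 9
    grid_shape: tuple = (8, 8, 8)
    n_timepoints: int = 200
    n_clips: int = 5
    a_shared: float = 0.15
    b_group_pre: float = 0.0
    b_group_post: float = 0.1
    affected_fraction: float = 0.125
    affected_block: tuple | None = None
    influence_weight: float = 0.0
    ar1: float = 0.0
    n_survey_items: int = 12
    survey_scale: int = 7
    seed: int = 0

    def __post_init__(self):
        self.group_sizes = tuple(int(s) for s in self.group_sizes)
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("group_sizes must be positive")
        if self.n_controls < 0:
            raise ValueError("n_controls must be >= 0")
        for name in ("a_shared", "b_group_pre", "b_group_post",
                     "affected_fraction", "influence_weight"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.a_shared + max(self.b_group_pre, self.b_group_post) \
            + self.influence_weight
        if total >= 1.0:
            raise ValueError(
                "variance fractions a_shared + max(b_group_pre, "
                f"b_group_post) + influence_weight = {total} must be < 1")
        if not (-1.0 < self.ar1 < 1.0):
            raise ValueError("ar1 must be in (-1, 1)")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.affected_block is not None:
            self.affected_block = tuple(int(s) for s in self.affected_block)
            if len(self.affected_block) != len(self.grid_shape) or any(
                    b > g for b, g in
                    zip(self.affected_block, self.grid_shape)):
                raise ValueError("affected_block does not fit grid_shape")

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes) + self.n_controls

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    def subject_ids(self) -> list:
        return [f"sub{s:03d}" for s in range(self.n_subjects)]

    def group_labels(self) -> list:
        labels = []
        for g, size in enumerate(self.group_sizes):
            labels += [f"g{g}"] * size
        labels += [CONTROL_LABEL] * self.n_controls
        return labels

    def affected_mask(self) -> np.ndarray:
        """Boolean mask (flat voxel axis) of the contiguous affected block.

        If ``affected_block`` is unset, a corner block of roughly
        ``affected_fraction`` of the grid volume is used (near-cubic,
        rounded per axis).
        """
        grid = np.zeros(self.grid_shape, dtype=bool)
        if self.affected_block is not None:
            block = self.affected_block
        else:
            side = self.affected_fraction ** (1.0 / len(self.grid_shape))
            block = tuple(max(1, int(round(s * side)))
                          for s in self.grid_shape)
        grid[tuple(slice(0, b) for b in block)] = True
        return grid.reshape(-1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SyntheticCohort:
    """Generated cohort bundle; ``truth`` round-trips through JSON and is
    sufficient to recompute every expected value used in recovery tests."""

    bold_pre: list          # list[BoldSession], one per clip
    bold_post: list
    network: "nx.DiGraph"
    surveys_pre: pd.DataFrame
    surveys_post: pd.DataFrame
    turns: pd.DataFrame
    truth: dict

    @property
    def subject_ids(self):
        return self.bold_pre[0].subject_ids

    @property
    def group_labels(self):
        return self.bold_pre[0].group_labels


def _noise(rng, shape, ar1: float) -> np.ndarray:
    """Unit-variance noise, optionally AR(1) along the last axis."""
    eps = rng.standard_normal(shape)
    if ar1 == 0.0:
        return eps
    from scipy.signal import lfilter
    out = lfilter([1.0], [1.0, -ar1], eps, axis=-1)
    return out * np.sqrt(1.0 - ar1 ** 2)


def generate_bold(config: SimulationConfig):
    """Generate per-clip pre and post BOLD sessions.

    Returns ``(bold_pre, bold_post)`` as lists of :class:`BoldSession`,
    one per clip.  Expected ISC at an affected voxel is
    ``a_shared + b_session`` within a group and ``a_shared`` between
    groups/controls; at unaffected voxels it is ``a_shared`` everywhere.
    """
    rng = np.random.default_rng(config.seed)
    n, v, t = config.n_subjects, config.n_voxels, config.n_timepoints
    labels = config.group_labels()
    ids = config.subject_ids()
    mask = config.affected_mask()
    group_index = {f"g{g}": g for g in range(config.n_groups)}
    memb = np.array([group_index.get(l, -1) for l in labels])

    pre, post = [], []
    for clip in range(config.n_clips):
        # the stimulus-driven components are properties of the clip, so
        # g and h are shared across the two viewings; only the noise is
        # redrawn and only the group weight b changes between sessions
        g = _noise(rng, (v, t), config.ar1)
        h = _noise(rng, (config.n_groups, v, t), config.ar1)
        sessions = {}
        for tag, b in (("pre", config.b_group_pre),
                       ("post", config.b_group_post)):
            eps = _noise(rng, (n, v, t), config.ar1)
            a = config.a_shared
            x = np.sqrt(a) * g[None] + np.sqrt(1.0 - a) * eps
            if b > 0.0:
                in_group = memb >= 0
                hg = h[memb[in_group]][:, mask, :]
                x[np.ix_(in_group, mask)] = (
                    np.sqrt(a) * g[None, mask]
                    + np.sqrt(b) * hg
                    + np.sqrt(1.0 - a - b) * eps[np.ix_(in_group, mask)])
            sessions[tag] = BoldSession(
                data=x, subject_ids=list(ids), group_labels=list(labels),
                clip_id=f"clip{clip}", grid_shape=config.grid_shape)
        pre.append(sessions["pre"])
        post.append(sessions["post"])
    return pre, post


def inject_influence(bold_pre: BoldSession, bold_post: BoldSession,
                     ego, alter, w: float,
                     seed: int = 0) -> BoldSession:
    """Plant directed ego -> alter imitation into one post session.

    The alter's post time series is replaced, per voxel, by
    ``sqrt(w) * ego_pre + sqrt(1 - w) * fresh_noise`` so that
    ``ISC(ego_pre, alter_post) = sqrt(w)`` in expectation (exactly 1 at
    ``w = 1``).  Returns a new post session; inputs are not modified.
    """
    if not (0.0 <= w <= 1.0):
        raise ValueError("w must be in [0, 1]")
    ids = list(bold_pre.subject_ids)
    if ego == alter:
        raise ValueError("ego and alter must differ")
    e, a = ids.index(ego), ids.index(alter)
    rng = np.random.default_rng(seed)
    data = bold_post.data.copy()
    noise = rng.standard_normal(bold_pre.data.shape[1:])
    data[a] = np.sqrt(w) * bold_pre.data[e] + np.sqrt(1.0 - w) * noise
    return BoldSession(data=data, subject_ids=ids,
                       group_labels=list(bold_post.group_labels),
                       clip_id=bold_post.clip_id,
                       tr_seconds=bold_post.tr_seconds,
                       grid_shape=bold_post.grid_shape)


def generate_network(n: int, model: str = "random-directed",
                     seed: int = 0, p: float = 0.3,
                     n_cliques: int = 2, clique_size: int = 4):
    """Synthetic directed friendship graph (simple, no self-loops).

    ``random-directed``: each ordered pair carries a nomination with
    probability ``p``.  ``clustered``: ``n_cliques`` mutually-nominating
    cliques of ``clique_size`` joined only through designated broker
    nodes (node attribute ``role='broker'``), giving a known
    high-brokerage ground truth; any remaining nodes attach to a random
    clique member.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    if model == "random-directed":
        mat = rng.random((n, n)) < p
        np.fill_diagonal(mat, False)
        g.add_edges_from(zip(*np.nonzero(mat)))
        g = nx.relabel_nodes(g, {i: int(i) for i in g.nodes})
    elif model == "clustered":
        need = n_cliques * clique_size
        n_brokers = max(1, n - need)
        if need + 1 > n:
            raise ValueError("n too small for requested cliques + broker")
        members = [list(range(c * clique_size, (c + 1) * clique_size))
                   for c in range(n_cliques)]
        for mem in members:
            for i in mem:
                for j in mem:
                    if i != j:
                        g.add_edge(i, j)
        brokers = list(range(need, need + n_brokers))
        for k, b in enumerate(brokers):
            g.nodes[b]["role"] = "broker"
            # one tie into each clique, reciprocated
            for mem in members:
                tgt = int(mem[int(rng.integers(len(mem)))])
                g.add_edge(b, tgt)
                g.add_edge(tgt, b)
    else:
        raise ValueError(f"unknown network model: {model!r}")
    return g


def generate_surveys(config: SimulationConfig, pull: float = 0.5,
                     seed: int | None = None):
    """Likert surveys that converge within groups after conversation.

    Pre answers are i.i.d. uniform integers on ``1..survey_scale`` per
    item per clip.  Post answers move toward the conversation-group mean
    by factor ``pull`` and are re-rounded to the integer scale; controls
    (and ``pull = 0``) keep their pre answers.  ``pull = 1`` collapses a
    group onto identical answer vectors.

    Returns ``(surveys_pre, surveys_post)`` as wide DataFrames indexed
    by ``(subject, clip)`` with one column per item.
    """
    if not (0.0 <= pull <= 1.0):
        raise ValueError("pull must be in [0, 1]")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ids = config.subject_ids()
    labels = config.group_labels()
    n_items = config.n_survey_items
    idx = pd.MultiIndex.from_product(
        [ids, [f"clip{c}" for c in range(config.n_clips)]],
        names=["subject", "clip"])
    cols = [f"item{i}" for i in range(n_items)]
    pre = pd.DataFrame(
        rng.integers(1, config.survey_scale + 1, (len(idx), n_items)),
        index=idx, columns=cols, dtype=float)
    post = pre.copy()
    lab = pd.Series(labels, index=ids)
    for grp, members in lab.groupby(lab).groups.items():
        if grp == CONTROL_LABEL:
            continue
        sel = pre.loc[list(members)]
        mean = sel.groupby(level="clip").mean()
        for clip in mean.index:
            block = pre.loc[(list(members), clip), :]
            moved = block + pull * (mean.loc[clip].values[None, :] - block)
            post.loc[(list(members), clip), :] = np.clip(
                np.round(moved), 1, config.survey_scale)
    return pre, post


def generate_turns(config: SimulationConfig, seed: int | None = None,
                   mean_turns: int = 30, status_talkativeness: float = 0.8,
                   vocab_size: int = 40, planted_stem: str = "plantstem",
                   planted_rate: float = 0.0,
                   status: pd.Series | None = None):
    """Per-turn speech table for the conversation-content analyses.

    Each group x clip conversation gets ~``mean_turns`` turns; speakers
    are drawn with weights increasing in perceived status (controlled by
    ``status_talkativeness``; 0 = equal turn-taking), so higher-status
    cohorts produce more unequal word counts.  Turns carry Poisson word
    counts and space-separated word stems drawn from a toy vocabulary;
    ``planted_stem`` is emitted at a rate proportional to the speaker's
    status when ``planted_rate > 0`` (a known word-use signal for the
    word-regression recovery tests).

    Returns a DataFrame with columns: turn_id, speaker, group, clip,
    n_words, stems, status.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    ids = config.subject_ids()
    labels = config.group_labels()
    lab = pd.Series(labels, index=ids)
    if status is None:
        status = pd.Series(rng.normal(0, 1, len(ids)), index=ids)
    vocab = [f"stem{i:02d}" for i in range(vocab_size)]
    rows = []
    tid = 0
    for grp, members in lab.groupby(lab).groups.items():
        if grp == CONTROL_LABEL:
            continue
        members = list(members)
        st = status.loc[members].values
        wgt = np.exp(status_talkativeness * st)
        wgt = wgt / wgt.sum()
        for clip in range(config.n_clips):
            n_turns = max(len(members), rng.poisson(mean_turns))
            speakers = rng.choice(members, size=n_turns, p=wgt)
            for sp in speakers:
                n_words = 1 + rng.poisson(8)
                k = max(1, rng.poisson(3))
                stems = list(rng.choice(vocab, size=k))
                if planted_rate > 0.0:
                    lam = planted_rate * max(
                        0.0, float(status.loc[sp]) + 1.0)
                    stems += [planted_stem] * rng.poisson(lam)
                rows.append({
                    "turn_id": tid, "speaker": sp, "group": grp,
                    "clip": f"clip{clip}", "n_words": int(n_words),
                    "stems": " ".join(stems),
                    "status": float(status.loc[sp])})
                tid += 1
    return pd.DataFrame(rows)


def generate_cohort(config: SimulationConfig, pull: float = 0.5,
                    network_model: str = "random-directed",
                    influence_pairs=None) -> SyntheticCohort:
    """Full cohort: BOLD (both sessions), network, surveys, turns, truth.

    ``influence_pairs`` is an optional list of ``(ego, alter)`` subject
    ids; each listed alter's post series (every clip) is overwritten by
    the ego-imitation mixture at ``config.influence_weight``.
    """
    bold_pre, bold_post = generate_bold(config)
    if influence_pairs:
        w = config.influence_weight
        for k, (ego, alter) in enumerate(influence_pairs):
            for c in range(config.n_clips):
                bold_post[c] = inject_influence(
                    bold_pre[c], bold_post[c], ego, alter, w,
                    seed=config.seed + 1000 + 97 * k + c)
    network = generate_network(config.n_subjects,
                               model=network_model,
                               seed=config.seed + 7)
    network = nx.relabel_nodes(
        network, dict(enumerate(config.subject_ids())))
    surveys_pre, surveys_post = generate_surveys(config, pull=pull,
                                                 seed=config.seed + 11)
    turns = generate_turns(config, seed=config.seed + 13)
    truth = {
        "config": config.to_dict(),
        "pull": pull,
        "network_model": network_model,
        "influence_pairs": [list(p) for p in (influence_pairs or [])],
        "affected_voxels": np.nonzero(config.affected_mask())[0].tolist(),
        "expected_isc_within_affected_pre":
            config.a_shared + config.b_group_pre,
        "expected_isc_within_affected_post":
            config.a_shared + config.b_group_post,
        "expected_isc_between": config.a_shared,
        "expected_influence_isc":
            float(np.sqrt(config.influence_weight)),
    }
    # normalize to JSON-native types so truth round-trips bit-identically
    truth = json.loads(json.dumps(truth))
    return SyntheticCohort(bold_pre=bold_pre, bold_post=bold_post,
                           network=network, surveys_pre=surveys_pre,
                           surveys_post=surveys_post, turns=turns,
                           truth=truth)
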