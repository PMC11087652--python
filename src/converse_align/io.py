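"""Cohort manifests, NIfTI/CSV readers and writers, run configuration
and the end-to-end pipeline.

A cohort on disk is a directory with per-subject 4-D NIfTI volumes (one
per session per clip), a friendship edge list (TSV), survey and turn
tables (CSV) and a ``manifest.json`` tying them together.  Every output
artifact embeds the run-config hash and seed, and the pipeline is a
pure function of ``(manifest, config)``: same inputs, byte-identical
summary tables.

Voxel coordinates are 0-based (i, j, k) in array order with row-major
flattening; NIfTI affines are carried through untouched.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import behavior as bh
from . import change as ch
from . import influence as infl
from . import network as net
from .isc import BoldSession, isc_matrix, cross_isc_matrix
from .simulate import CONTROL_LABEL, SyntheticCohort

__all__ = ["RunConfig", "CohortManifest", "write_cohort", "load_cohort",
           "run_full_pipeline"]

log = logging.getLogger("converse_align")


@dataclass
class RunConfig:
    """All analysis knobs in one serializable place.

    The defaults mirror the analysis conventions: 2000 subject-wise
    permutations, cluster-forming p = 0.01 with a 32-voxel minimum
    extent at face (6-)connectivity, a 10-TR rolling window, raw-r ISC
    (no Fisher z), add-one-smoothed permutation p-values, and per-group
    predictor columns.
    """

    n_perm: int = 2000
    cluster_forming_p: float = 0.01
    min_cluster_size: int = 32
    connectivity: int = 6
    window: int = 10
    window_step: int = 1
    fisher_z: bool = False
    smoothing: bool = True
    design_mode: str = "per_group"
    centrality_metrics: tuple = ("pca",)
    directed_network: bool = False
    word_min_total: int = 5
    word_min_speakers: int = 10
    word_min_clips: int = 3
    behavior_n_perm: int = 200
    use_cluster_null: bool = False
    seed: int = 0

    def __post_init__(self):
        self.centrality_metrics = tuple(self.centrality_metrics)
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.cluster_forming_p < 1):
            raise ValueError("cluster_forming_p must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["centrality_metrics"] = list(d["centrality_metrics"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class CohortManifest:
    """Parsed, path-validated view of a cohort directory."""

    root: Path
    subjects: list
    group_labels: dict
    clips: list
    grid_shape: tuple
    tr_seconds: float
    bold: dict            # clip -> session -> subject -> relative path
    network_path: str
    surveys_pre_path: str
    surveys_post_path: str
    turns_path: str
    truth: dict
    seed_registry: dict

    @classmethod
    def load(cls, path) -> "CohortManifest":
        path = Path(path)
        with open(path) as fh:
            d = json.load(fh)
        root = path.parent
        man = cls(root=root, subjects=d["subjects"],
                  group_labels=d["group_labels"], clips=d["clips"],
                  grid_shape=tuple(d["grid_shape"]),
                  tr_seconds=d.get("tr_seconds", 1.0), bold=d["bold"],
                  network_path=d["network"],
                  surveys_pre_path=d["surveys_pre"],
                  surveys_post_path=d["surveys_post"],
                  turns_path=d["turns"], truth=d.get("truth", {}),
                  seed_registry=d.get("seed_registry", {}))
        for rel in man.iter_paths():
            if not (root / rel).exists():
                raise FileNotFoundError(f"manifest references missing "
                                        f"file: {rel}")
        return man

    def iter_paths(self):
        for clip in self.clips:
            for ses in ("pre", "post"):
                for sub, rel in self.bold[clip][ses].items():
                    yield rel
        yield self.network_path
        yield self.surveys_pre_path
        yield self.surveys_post_path
        yield self.turns_path


def _nifti_path(sub: str, ses: str, clip: str) -> str:
    return f"bold/{sub}_{ses}_{clip}.nii.gz"


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Serialize a cohort: NIfTI volumes, CSV tables, TSV edge list and
    manifest.json.  Returns the manifest path."""
    outdir = Path(outdir)
    (outdir / "bold").mkdir(parents=True, exist_ok=True)
    ids = list(cohort.subject_ids)
    labels = list(cohort.group_labels)
    clips = [s.clip_id for s in cohort.bold_pre]
    grid = cohort.bold_pre[0].grid_shape
    if grid is None:
        raise ValueError("cohort sessions lack grid_shape")
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    bold = {}
    for pre, post in zip(cohort.bold_pre, cohort.bold_post):
        clip = pre.clip_id
        bold[clip] = {"pre": {}, "post": {}}
        for ses, session in (("pre", pre), ("post", post)):
            for si, sub in enumerate(ids):
                rel = _nifti_path(sub, ses, clip)
                vol = session.data[si].reshape(*grid, -1)
                nib.save(nib.Nifti1Image(vol.astype(np.float64), affine),
                         outdir / rel)
                bold[clip][ses][sub] = rel
    net.write_edge_list(cohort.network, outdir / "network.tsv")
    cohort.surveys_pre.to_csv(outdir / "surveys_pre.csv")
    cohort.surveys_post.to_csv(outdir / "surveys_post.csv")
    cohort.turns.to_csv(outdir / "turns.csv", index=False)
    manifest = {
        "subjects": ids,
        "group_labels": dict(zip(ids, labels)),
        "clips": clips,
        "grid_shape": list(grid),
        "tr_seconds": cohort.bold_pre[0].tr_seconds,
        "bold": bold,
        "network": "network.tsv",
        "surveys_pre": "surveys_pre.csv",
        "surveys_post": "surveys_post.csv",
        "turns": "turns.csv",
        "truth": cohort.truth,
        "seed_registry": {"cohort": cohort.truth.get(
            "config", {}).get("seed")},
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def _load_nifti_series(path: Path, grid_shape) -> np.ndarray:
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:
        raise ValueError(f"unreadable NIfTI volume {path.name}: "
                         f"{exc}") from exc
    if data.ndim != 4 or data.shape[:3] != tuple(grid_shape):
        raise ValueError(f"{path.name}: expected 4-D volume with grid "
                         f"{tuple(grid_shape)}, got shape {data.shape}")
    if np.isnan(data).all():
        raise ValueError(f"{path.name}: volume is entirely NaN")
    return data.reshape(-1, data.shape[3])


def load_cohort(manifest_path) -> SyntheticCohort:
    """Load and validate a cohort directory back into memory.

    Checks dimension and label consistency: every survey/turn subject
    must appear in the manifest, every volume must match the grid.
    """
    man = CohortManifest.load(manifest_path)
    ids = man.subjects
    labels = [man.group_labels[s] for s in ids]
    known = set(ids)
    surveys_pre = pd.read_csv(man.root / man.surveys_pre_path,
                              index_col=["subject", "clip"])
    surveys_post = pd.read_csv(man.root / man.surveys_post_path,
                               index_col=["subject", "clip"])
    for name, df in (("surveys_pre", surveys_pre),
                     ("surveys_post", surveys_post)):
        extra = set(df.index.get_level_values("subject")) - known
        if extra:
            raise ValueError(f"{name} contains unknown subjects: "
                             f"{sorted(extra)}")
    turns = pd.read_csv(man.root / man.turns_path)
    extra = set(turns["speaker"]) - known
    if extra:
        raise ValueError(f"turns contain unknown speakers: "
                         f"{sorted(extra)}")
    graph = net.read_edge_list(man.root / man.network_path)
    bold_pre, bold_post = [], []
    for clip in man.clips:
        sessions = {}
        for ses in ("pre", "post"):
            data = np.stack([
                _load_nifti_series(man.root / man.bold[clip][ses][s],
                                   man.grid_shape) for s in ids])
            sessions[ses] = BoldSession(
                data=data, subject_ids=list(ids),
                group_labels=list(labels), clip_id=clip,
                tr_seconds=man.tr_seconds, grid_shape=man.grid_shape)
        bold_pre.append(sessions["pre"])
        bold_post.append(sessions["post"])
    return SyntheticCohort(bold_pre=bold_pre, bold_post=bold_post,
                           network=graph, surveys_pre=surveys_pre,
                           surveys_post=surveys_post, turns=turns,
                           truth=man.truth)


def _stage(name):
    log.info("stage %s", name)
    return time.perf_counter()


def run_full_pipeline(cohort, config: RunConfig, outdir) -> dict:
    """Run every analysis stage on a cohort and write the report bundle.

    ``cohort`` is a SyntheticCohort or a manifest path.  Writes, under
    ``outdir``: cluster table, beta summary, whole-brain alignment and
    influence tables, centrality table, behavior summary and a markdown
    report carrying the config hash and seed.  Returns the tables plus
    a dict of their SHA-256 hashes (the determinism contract).
    """
    if not isinstance(cohort, SyntheticCohort):
        cohort = load_cohort(cohort)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    ids = list(cohort.subject_ids)
    labels = list(cohort.group_labels)
    clips = [s.clip_id for s in cohort.bold_pre]
    grid = cohort.bold_pre[0].grid_shape

    t0 = _stage("isc+change")
    pre_stacks, changes, finals = {}, [], {}
    for pre, post in zip(cohort.bold_pre, cohort.bold_post):
        ipre = isc_matrix(pre, fisher_z=config.fisher_z)
        ipost = isc_matrix(post, fisher_z=config.fisher_z)
        pre_stacks[pre.clip_id] = ipre
        changes.append(ch.change_stack(ipre, ipost))
        finals[pre.clip_id] = cross_isc_matrix(pre, post,
                                               fisher_z=config.fisher_z)
    design = ch.build_design(labels, clips, mode=config.design_mode,
                             subject_ids=ids)
    maps = ch.fit_pairwise_regression(changes, design)
    perm = ch.subjectwise_permutation(changes, design,
                                      n_perm=config.n_perm,
                                      seed=config.seed,
                                      smoothing=config.smoothing,
                                      keep_null=config.use_cluster_null)
    null_sizes = None
    if config.use_cluster_null:
        pred = maps.names[1] if len(maps.names) > 1 else maps.names[0]
        null_sizes = ch.max_cluster_null(
            perm, grid, pred, config.cluster_forming_p,
            config.connectivity)
    clusters = ch.cluster_correct(
        maps, perm, grid_shape=grid,
        cluster_forming_p=config.cluster_forming_p,
        min_size=config.min_cluster_size,
        connectivity=config.connectivity,
        null_max_sizes=null_sizes, seed=config.seed)
    alignment = ch.whole_brain_alignment(changes)
    log.info("change stage done in %.1fs", time.perf_counter() - t0)

    t0 = _stage("influence+network")
    cent = net.centrality_table(cohort.network,
                                directed=config.directed_network)
    infl_stacks = [infl.influence_stack(pre_stacks[c], finals[c])
                   for c in clips]
    wb_influence = infl.whole_brain_influence(infl_stacks)
    cent_design = infl.build_centrality_design(
        labels, clips, cent, ids, metrics=config.centrality_metrics)
    infl_maps = infl.fit_influence_regression(infl_stacks, cent_design)
    log.info("influence stage done in %.1fs", time.perf_counter() - t0)

    t0 = _stage("behavior")
    lab = pd.Series(labels, index=ids)
    surveys = bh.session_group_design(
        cohort.surveys_pre, cohort.surveys_post, lab,
        n_perm=config.behavior_n_perm, seed=config.seed)
    feats = bh.group_features(
        cohort.turns, centrality=cent["pca"],
        status=cohort.turns.set_index("speaker")["status"].groupby(
            level=0).first())
    stems = bh.word_stem_matrix(cohort.turns.set_index("turn_id")
                                .reset_index(),
                                min_total=config.word_min_total,
                                min_speakers=config.word_min_speakers,
                                min_clips=config.word_min_clips)
    log.info("behavior stage done in %.1fs", time.perf_counter() - t0)

    beta_summary = pd.DataFrame(maps.betas, columns=maps.names)
    beta_summary.insert(0, "voxel", np.arange(len(beta_summary)))
    infl_summary = pd.DataFrame(infl_maps.betas, columns=infl_maps.names)
    infl_summary.insert(0, "voxel", np.arange(len(infl_summary)))
    behavior_summary = pd.DataFrame([{
        "marginal_r2": surveys["marginal_r2"],
        "p_marginal_r2": surveys["p_marginal_r2"],
        **{f"coef_{k}": v
           for k, v in surveys["coefficients"].items()},
        "n_surviving_stems": stems.shape[1],
    }])

    tables = {
        "clusters": clusters,
        "change_betas": beta_summary,
        "influence_betas": infl_summary,
        "whole_brain_alignment": alignment,
        "whole_brain_influence": wb_influence,
        "centrality": cent.reset_index(names="subject"),
        "group_features": feats,
        "behavior_summary": behavior_summary,
    }
    hashes = {}
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    report = [
        "# Analysis report",
        f"- config hash: {cfg_hash}",
        f"- seed: {config.seed}",
        f"- subjects: {len(ids)}; clips: {len(clips)}; "
        f"voxels: {int(np.prod(grid))}",
        f"- permutations: {perm.n_permutations}",
        f"- significant clusters: {len(clusters)}",
        "",
        "## Table hashes",
    ] + [f"- {k}: {v}" for k, v in sorted(hashes.items())]
    (outdir / "report.md").write_text("\n".join(report) + "\n")
    with open(outdir / "run_config.json", "w") as fh:
        json.dump({"config": config.to_dict(), "hash": cfg_hash},
                  fh, indent=1, sort_keys=True)
    return {"tables": tables, "hashes": hashes, "config_hash": cfg_hash,
            "maps": maps, "permutation": perm}
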