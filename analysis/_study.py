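"""Shared study configuration for the analysis drivers.

The synthetic study mirrors the target design: 49 subjects (9
conversation groups of 3-6 plus 9 controls), 5 clips viewed in two
sessions, a desk-scale 8x8x8 voxel grid with a contiguous 4x4x4 block
carrying the planted group-convergence signal.
"""

from pathlib import Path

import converse_align as ca

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

STUDY_SEED = 20240

STUDY_CONFIG = ca.SimulationConfig(
    group_sizes=(4, 4, 4, 4, 4, 4, 5, 5, 6), n_controls=9,
    grid_shape=(8, 8, 8), n_timepoints=200, n_clips=5,
    a_shared=0.15, b_group_pre=0.0, b_group_post=0.1,
    affected_block=(4, 4, 4), seed=STUDY_SEED)


def study_cohort():
    """Generate (or reload from scratch/, if serialized) the cohort."""
    manifest = SCRATCH / "cohort" / "manifest.json"
    if manifest.exists():
        return ca.load_cohort(manifest)
    return ca.generate_cohort(STUDY_CONFIG, pull=0.5)
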