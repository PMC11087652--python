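import numpy as np
import pandas as pd
import pytest

import converse_align as ca


@pytest.fixture(scope="session")
def small_config():
    """Two groups of three plus two controls; tiny grid; planted
    convergence of known size b_post - b_pre = 0.25."""
    return ca.SimulationConfig(
        group_sizes=(3, 3), n_controls=2, grid_shape=(4, 4, 4),
        n_timepoints=150, n_clips=2, a_shared=0.15, b_group_pre=0.05,
        b_group_post=0.30, affected_block=(2, 2, 2), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return ca.generate_cohort(small_config, pull=0.6)


@pytest.fixture(scope="session")
def tiny_session():
    """Three subjects, two voxels, hand-checkable series."""
    rng = np.random.default_rng(0)
    data = rng.standard_normal((3, 2, 12))
    return ca.BoldSession(data=data, subject_ids=["a", "b", "c"],
                          group_labels=["g0", "g0", "g1"])


def brute_force_isc_matrix(session):
    """Oracle: scalar pairwise_isc looped over every pair and voxel."""
    n, v, _ = session.data.shape
    out = np.ones((v, n, n))
    for vox in range(v):
        for i in range(n):
            for j in range(n):
                out[vox, i, j] = ca.pairwise_isc(session.data[i, vox],
                                                 session.data[j, vox])
    return out


def normal_equation_betas(x, y):
    """Oracle: closed-form (X'X)^-1 X'y, independent of lstsq."""
    return np.linalg.solve(x.T @ x, x.T @ y)
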