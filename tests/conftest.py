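"""Shared fixtures: cells, point groups and small simulated datasets."""

import numpy as np
import pandas as pd
import pytest

from ssrox.crystal import PointGroup, UnitCell
from ssrox.simulate import (
    DamageModel,
    HeavyAtomSite,
    SimConfig,
    generate_ground_truth,
    simulate_experiment,
)

MAJOR_SITE = (0.1, 0.2, 0.3)
MINOR_SITE = (0.4, 0.15, 0.62)


@pytest.fixture(scope="session")
def cell():
    return UnitCell(47.3, 76.7, 84.0)


@pytest.fixture(scope="session")
def small_cell():
    return UnitCell(10.0, 12.0, 14.0)


@pytest.fixture(scope="session")
def pg222():
    return PointGroup(name="222")


@pytest.fixture(scope="session")
def pg1():
    return PointGroup(name="1")


@pytest.fixture(scope="session")
def sites():
    return [
        HeavyAtomSite(frac_xyz=MAJOR_SITE, occupancy=1.0),
        HeavyAtomSite(frac_xyz=MINOR_SITE, occupancy=0.3),
    ]


@pytest.fixture(scope="session")
def small_truth(small_cell, pg222, sites):
    """Fast ground truth in a toy cell for exact-arithmetic tests."""
    return generate_ground_truth(small_cell, pg222, d_min=2.0, sites=sites, seed=1,
                                 n_dummy_atoms=20)


@pytest.fixture(scope="session")
def truth(cell, pg222, sites):
    """Study-scale ground truth (two Hg-like sites, 3.5 Å limit)."""
    return generate_ground_truth(cell, pg222, d_min=3.5, sites=sites, seed=7)


@pytest.fixture(scope="session")
def noisefree_run(truth):
    """Noise-free, unit-scale simulation: observations are exactly p·L·I_true."""
    config = SimConfig(
        n_frames=40, hit_fraction=1.0, crystal_scale_sigma=0.0,
        noise_b0=0.0, poisson_gain=0.0, seed=5,
    )
    frames, obs = simulate_experiment(truth, config)
    return frames, obs, config


@pytest.fixture(scope="session")
def noisy_run(truth):
    """A modest noisy run used by several statistics tests."""
    config = SimConfig(n_frames=300, hit_fraction=0.5, seed=11)
    frames, obs = simulate_experiment(truth, config)
    return frames, obs, config


@pytest.fixture(scope="session")
def truth_phase_lookup(truth):
    """Series mapping ASU (h,k,l) to the ground-truth model phase."""
    return pd.Series(
        truth.phases, index=pd.MultiIndex.from_arrays(truth.hkl.T)
    )


def true_intensity_lookup(truth, dose=0.0):
    """Dict (h,k,l,friedel) -> true intensity, for round-trip comparisons."""
    ip, im = truth.intensities(dose)
    out = {}
    for i, (h, k, l) in enumerate(truth.hkl):
        out[(h, k, l, 1)] = ip[i]
        out[(h, k, l, -1)] = im[i]
    return out
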