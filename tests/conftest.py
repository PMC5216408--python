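"""Shared fixtures: a desk-scale simulation configuration and tiny cohorts.

Everything is generated programmatically at test time; no data files are
shipped.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from alffdev.synthetic import (
    CohortSpec,
    RegionEffectSpec,
    SimulationConfig,
    generate_dataset,
    make_masks,
)


def tiny_sim_config(**overrides) -> SimulationConfig:
    """A miniature grid (12x14x12, 60 volumes) that keeps every stage fast."""
    regions = [
        RegionEffectSpec(
            "mPFC", (6, 11, 8), radius_vox=2.0,
            amplitude={"TC": (2.21, -0.11, 0.0025), "ASD": (1.18, 0.0, 0.0)},
        ),
        RegionEffectSpec(
            "precuneus", (8, 3, 8), radius_vox=2.0,
            amplitude={"TC": (1.0, 0.0, 0.0), "ASD": (0.88, 0.0, 0.0)},
        ),
        RegionEffectSpec(
            "MOG", (4, 3, 4), radius_vox=1.6,
            amplitude={"TC": (1.0, 0.0, 0.0), "ASD": (0.88, 0.0, 0.0)},
        ),
    ]
    cfg = SimulationConfig(
        grid_dims=(12, 14, 12),
        n_volumes=60,
        regions=regions,
        brain_axes_vox=(5.0, 6.0, 5.0),
        wm_axes_vox=(2.2, 2.6, 2.2),
        csf_axes_vox=(1.0, 1.2, 1.0),
    )
    return replace(cfg, **overrides) if overrides else cfg


def tiny_cohort_spec(n_per_cell: int = 2, seed: int = 0) -> CohortSpec:
    cells = {(d, c): n_per_cell for d in ("ASD", "TC")
             for c in ("child", "adolescent", "adult")}
    return CohortSpec(cell_sizes=cells, seed=seed)


@pytest.fixture(scope="session")
def sim_config():
    return tiny_sim_config()

@pytest.fixture(scope="session")
def masks(sim_config):
    return make_masks(sim_config)


@pytest.fixture(scope="session")
def tiny_dataset(sim_config):
    """A fully materialized 12-subject cohort on the miniature grid."""
    return generate_dataset(tiny_cohort_spec(), sim_config, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
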