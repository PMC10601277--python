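"""Shared fixtures: one small deterministic cohort reused across modules."""

import numpy as np
import pandas as pd
import pytest

from methsig.simulate import (
    SimConfig,
    make_bin_counts,
    make_cohort_meta,
    make_probe_betas,
    make_unit_table,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_samples_per_arm=12,
        n_bins=800,
        n_planted_dmrs_exp=10,
        n_planted_dmrs_std=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def cohort(small_cfg):
    meta = make_cohort_meta(small_cfg)
    m, truth = make_bin_counts(small_cfg, meta)
    return meta, m, truth


@pytest.fixture(scope="session")
def platforms(small_cfg, cohort):
    meta, _, truth = cohort
    panel, betas, theta = make_probe_betas(small_cfg, truth, meta)
    units, unit_to_probe = make_unit_table(small_cfg, panel, theta, meta)
    return panel, betas, theta, units, unit_to_probe


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
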