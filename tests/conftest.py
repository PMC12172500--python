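"""Shared fixtures: small synthetic cohorts built once per session."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import mischkit as mk


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort (24 subjects) for fast structural tests."""
    cfg = mk.default_config()
    return replace(
        cfg,
        n_subjects={"Healthy": 10, "AGA3": 6, "AGA5": 4, "AGA7": 4},
        depth=20_000,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return mk.simulate_cohort(small_config, seed=101)


@pytest.fixture(scope="session")
def small_merged(small_cohort):
    bact, fungi, _ = small_cohort
    return mk.merge_kingdoms(bact, fungi)


@pytest.fixture(scope="session")
def study_cohort():
    """The default 89-subject, 178-sample cohort."""
    return mk.simulate_cohort(seed=11)


@pytest.fixture(scope="session")
def study_merged(study_cohort):
    bact, fungi, _ = study_cohort
    return mk.merge_kingdoms(bact, fungi)


@pytest.fixture()
def tiny_table():
    """A hand-sized 3x4 normalized table."""
    data = pd.DataFrame(
        [
            [0.5, 0.5, 0.0, 0.0],
            [0.25, 0.25, 0.25, 0.25],
            [0.1, 0.2, 0.3, 0.4],
        ],
        index=["s1", "s2", "s3"],
        columns=["ga", "gb", "gc", "gd"],
    )
    return mk.AbundanceTable(data, "bacteria", "genus")


def random_table(rng, n_samples=8, n_taxa=5, kingdom="bacteria"):
    """Seeded random normalized table for property checks."""
    vals = rng.dirichlet(np.ones(n_taxa), size=n_samples)
    df = pd.DataFrame(
        vals,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"{kingdom[:1]}t{j}" for j in range(n_taxa)],
    )
    return mk.AbundanceTable(df, kingdom, "genus")
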