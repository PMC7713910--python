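"""Shared fixtures: the worked-example carabid taxonomy and session-scoped
synthetic datasets/reports reused by several test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from pitfallid import synthetic_data
from pitfallid.cli import reduced_experiment_config, run_experiment_frames
from pitfallid.taxonomy import DEFAULT_RANKS, TaxonomyTable

# Real carabid taxa used as a readable worked-example fixture.  Each species
# is its own "group" (placeholder convention for taxa without a species
# group); Pterostichini is recorded at the subtribe rank, shared by
# Pterostichus and Cyclotrachelus.
CARABID_ROWS = [
    # species, genus, subtribe, tribe, subfamily
    ("Pasimachus strenuus", "Pasimachus", "Pasimachina", "Scaritini", "Scaritinae"),
    ("Pasimachus californicus", "Pasimachus", "Pasimachina", "Scaritini", "Scaritinae"),
    ("Scarites subterraneus", "Scarites", "Scaritina", "Scaritini", "Scaritinae"),
    ("Cyclotrachelus torvus", "Cyclotrachelus", "Pterostichini", "Pterostichini", "Harpalinae"),
    ("Cyclotrachelus furtivus", "Cyclotrachelus", "Pterostichini", "Pterostichini", "Harpalinae"),
    ("Pterostichus melanarius", "Pterostichus", "Pterostichini", "Pterostichini", "Harpalinae"),
    ("Pterostichus trinarius", "Pterostichus", "Pterostichini", "Pterostichini", "Harpalinae"),
    ("Chlaenius aestivus", "Chlaenius", "Chlaeniina", "Chlaeniini", "Harpalinae"),
]


def carabid_frame() -> pd.DataFrame:
    rows = [
        {
            "species": sp,
            "group": sp,
            "genus": gen,
            "subtribe": sub,
            "tribe": tri,
            "subfamily": fam,
        }
        for sp, gen, sub, tri, fam in CARABID_ROWS
    ]
    return pd.DataFrame(rows, columns=list(DEFAULT_RANKS))


@pytest.fixture(scope="session")
def carabid_taxonomy() -> TaxonomyTable:
    return TaxonomyTable(table=carabid_frame())


@pytest.fixture(scope="session")
def reduced_dataset():
    """Taxonomy, feature table and site pools at the reduced study scale."""
    return synthetic_data.generate_dataset(synthetic_data.REDUCED_PRESET)


@pytest.fixture(scope="session")
def reduced_report(reduced_dataset):
    """Full end-to-end evaluation report on the reduced preset (all five
    algorithms, 10 repeats, every protocol)."""
    tax, table, pools = reduced_dataset
    cfg = reduced_experiment_config(seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_experiment_frames(table, tax, pools, cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
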