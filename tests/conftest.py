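import csv
from pathlib import Path

import numpy as np
import pytest

from agrimeta.effects import EffectSize, effects_from_records
from agrimeta.io import COLUMNS
from agrimeta.simulate import SimulationConfig, simulate_meta_dataset

GOOD_ROW = {
    "publication_id": "pub1",
    "observation_id": "obs1",
    "pub_year": "2005",
    "country": "SE",
    "region": "Uppland",
    "taxon_group": "plants",
    "functional_group": "producers",
    "crop_type": "cereals",
    "scale": "field",
    "mean_org": "12.5",
    "sd_org": "3.1",
    "n_org": "8",
    "mean_conv": "9.4",
    "sd_conv": "2.7",
    "n_conv": "8",
    "pct_arable": "55.0",
    "n_habitats": "4",
    "avg_field_size": "6.2",
}


def write_csv(path: Path, rows, columns=COLUMNS):
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns), extrasaction="ignore")
        writer.writeheader()
        writer.writerows(rows)
    return path


@pytest.fixture
def study_csv(tmp_path):
    """Factory writing study CSVs built from GOOD_ROW overrides."""

    def make(rows_overrides, name="table.csv", columns=COLUMNS):
        rows = [{**GOOD_ROW, **ov} for ov in rows_overrides]
        return write_csv(tmp_path / name, rows, columns)

    return make


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset (~60 effects) shared across tests."""
    cfg = SimulationConfig(n_publications=30, seed=7)
    records, truth = simulate_meta_dataset(cfg)
    return records, truth


@pytest.fixture(scope="session")
def small_effects(small_dataset):
    records, _ = small_dataset
    return effects_from_records(records)


@pytest.fixture
def fast_fit_kwargs():
    """Coarser grid for speed-sensitive pipeline tests."""
    return {"tau_grid_size": 61}


def make_effects(ys, vs, pubs=None):
    pubs = pubs or [f"p{i}" for i in range(len(ys))]
    return [
        EffectSize(y=float(y), v=float(v), publication_id=p, observation_id=f"o{i}")
        for i, (y, v, p) in enumerate(zip(ys, vs, pubs))
    ]


@pytest.fixture
def effects_factory():
    return make_effects
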