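"""Shared fixtures: small hand-made trait tables and one simulated dataset."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import traitbef as tb


@pytest.fixture(scope="session")
def dataset() -> tb.SimulatedDataset:
    """One default-scenario synthetic experiment, reused across tests."""
    return tb.simulate_dataset(seed=20120518)


@pytest.fixture(scope="session")
def predictor_matrix(dataset) -> tb.PredictorMatrix:
    table = tb.transform_traits(dataset.traits)
    comps = [
        c
        for c in tb.compositions_from_table(dataset.mixture)
        if len(c.species_ids) >= 2
    ]
    return tb.build_predictor_matrix(comps, table)


@pytest.fixture(scope="session")
def community_biomass(dataset, predictor_matrix) -> np.ndarray:
    totals = dataset.mixture.groupby("plot_id", sort=False)["biomass"].sum()
    return totals.reindex(predictor_matrix.plot_ids).to_numpy()


def write_small_trait_files(tmp_path, values=None, groups=None):
    """A 3-species, 2-trait table on disk (CSV + YAML metadata)."""
    tmp_path.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        values
        if values is not None
        else {"m.seed": [1.0, 10.0, 100.0], "SLA": [20.0, 25.0, 30.0]},
        index=["sp1", "sp2", "sp3"],
    )
    df.insert(0, "group", groups if groups is not None else ["grass", "legume", "tall_herb"])
    path = tmp_path / "traits.csv"
    df.to_csv(path, index_label="species_id")
    meta = tmp_path / "meta.yaml"
    meta.write_text(
        "traits:\n"
        "- {name: seed mass, abbreviation: m.seed, value_kind: continuous, "
        "log_transform: true, source: measurement}\n"
        "- {name: specific leaf area, abbreviation: SLA, value_kind: continuous, "
        "log_transform: false, source: measurement}\n"
    )
    return path, meta


@pytest.fixture()
def small_trait_files(tmp_path):
    return write_small_trait_files(tmp_path)


def random_predictors(rng: np.random.Generator, n: int = 66, p: int = 18) -> tb.PredictorMatrix:
    """A synthetic predictor matrix with independent columns (fd >= 0)."""
    names = [f"t{k:02d}" for k in range(p)]
    cwm = pd.DataFrame(rng.normal(size=(n, p)), columns=names,
                       index=[f"P{i:03d}" for i in range(n)])
    fd = pd.DataFrame(rng.gamma(shape=2.0, scale=0.5, size=(n, p)), columns=names,
                      index=cwm.index)
    return tb.PredictorMatrix(
        plot_ids=list(cwm.index), cwm=cwm, fd=fd, trait_abbrevs=names
    )
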