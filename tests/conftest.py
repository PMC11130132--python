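import numpy as np
import pandas as pd
import pytest

from nichescape.phylo_core import parse_tree
from nichescape.schema import CATEGORICAL_LEVELS, raw_schema
from nichescape.synthetic_data import StudyConfig, simulate_study
from nichescape.trait_data import TraitTable


def random_mixed_table(rng, n_species=12, n_quant=4,
                       cat_levels=(("a", "b"), ("x", "y", "z"))):
    """A small random table with the mixed typing the factor analysis needs."""
    from nichescape.schema import TraitSchema

    idx = pd.Index([f"s{i:03d}" for i in range(n_species)], name="species_id")
    data = {}
    quant = tuple(f"q{j}" for j in range(n_quant))
    for q in quant:
        data[q] = rng.normal(size=n_species) * rng.uniform(0.5, 3.0)
    categorical = {}
    for ci, levels in enumerate(cat_levels):
        name = f"c{ci}"
        # guarantee every level appears at least once
        vals = list(levels) + list(rng.choice(levels, size=n_species - len(levels)))
        rng.shuffle(vals)
        data[name] = vals
        categorical[name] = tuple(levels)
    schema = TraitSchema(continuous=quant, categorical=categorical)
    return TraitTable(pd.DataFrame(data, index=idx), schema)


@pytest.fixture(scope="session")
def small_study():
    """A 60-species, 5-tree synthetic study, shared across tests."""
    table, trees, truth = simulate_study(
        StudyConfig(n_species=60, n_trees=5), seed=11
    )
    return table, trees, truth


@pytest.fixture()
def toy_tree():
    """((A:1,B:1):1,C:2); — the worked covariance example."""
    return parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture()
def raw_csv(tmp_path, small_study):
    table, _, _ = small_study
    path = tmp_path / "traits.csv"
    table.write_csv(path)
    return path


def assert_valid_raw_table(table):
    schema = raw_schema()
    assert set(schema.variables) <= set(table.data.columns)
    for var, levels in CATEGORICAL_LEVELS.items():
        assert set(table.data[var]) <= set(levels)
    assert np.isfinite(table.continuous_frame().to_numpy()).all()
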