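import numpy as np
import pandas as pd
import pytest

from oatmet import CellMeanMatrix, MetTable, datasets


@pytest.fixture(scope="session")
def trial_environments():
    return datasets.load_trial_environments()


@pytest.fixture(scope="session")
def env_quality():
    return datasets.load_environment_quality_means()


@pytest.fixture(scope="session")
def env_dimensions():
    return datasets.load_environment_dimension_means()


@pytest.fixture(scope="session")
def env_means(env_quality, env_dimensions):
    return env_quality.join(env_dimensions)


@pytest.fixture(scope="session")
def variety_summary():
    return datasets.load_variety_summary()


@pytest.fixture
def small_met():
    """1 trait, 2 environments x 2 varieties x 2 replicates, balanced."""
    rows = []
    values = {
        ("e1", "a"): (2.0, 4.0),
        ("e1", "b"): (6.0, 8.0),
        ("e2", "a"): (3.0, 5.0),
        ("e2", "b"): (7.0, 9.0),
    }
    for (env, var), reps in values.items():
        for k, v in enumerate(reps, start=1):
            rows.append(
                dict(environment=env, variety=var, replicate=k, trait="yield", value=v)
            )
    return MetTable(pd.DataFrame(rows))


@pytest.fixture
def met_csv(tmp_path):
    """Write a long-format phenotype CSV and return its path."""

    def _write(rows, name="pheno.csv"):
        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    return _write


def dense_cells(values, **kwargs):
    return CellMeanMatrix.from_dense(np.asarray(values, dtype=float), **kwargs)


@pytest.fixture
def make_cells():
    return dense_cells
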