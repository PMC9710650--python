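import numpy as np
import pandas as pd
import pytest

from proteoflow.io_maxquant import IntensityTable
from proteoflow import synthetic_fixtures as sf


def make_table(matrix, samples=None, proteins=None, flavor="raw") -> IntensityTable:
    """IntensityTable from a plain array (NaN = missing)."""
    matrix = np.asarray(matrix, dtype=float)
    samples = samples or [f"s{j+1}" for j in range(matrix.shape[1])]
    proteins = proteins or [f"p{i+1}" for i in range(matrix.shape[0])]
    return IntensityTable(
        pd.DataFrame(matrix, index=proteins, columns=samples), flavor
    )


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """Small benchmark-style dataset: 200 proteins, 2×3×2 design."""
    path = tmp_path_factory.mktemp("fixture") / "proteinGroups.txt"
    spec = sf.FixtureSpec(n_proteins=200, seed=7)
    frame, truth = sf.generate(spec, path)
    return path, spec, truth


@pytest.fixture(scope="session")
def clean_fixture(tmp_path_factory):
    """Two groups × 4 replicates, no dropout, no flagged rows, planted
    1-log2-unit effects in the 'stim' group."""
    path = tmp_path_factory.mktemp("clean") / "proteinGroups.txt"
    spec = sf.FixtureSpec(
        n_proteins=500,
        lines=("ctrl", "stim"),
        treatments=(),
        replicates=4,
        dropout=False,
        contaminant_fraction=0.0,
        reverse_fraction=0.0,
        site_fraction=0.0,
        effect_group="stim",
        seed=11,
    )
    frame, truth = sf.generate(spec, path)
    return path, spec, truth
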