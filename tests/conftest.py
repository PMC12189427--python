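import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from recland.coordinates import ChromosomeModel, build_interval_grid
from recland.recmap import FocusTable
from recland.synthetic_data import GenomeSimParams, simulate_genome


@pytest.fixture
def chr1_guinea_fowl() -> ChromosomeModel:
    """The worked example: 194.4 Mb assembly, mean SC length 24.5 um."""
    return ChromosomeModel(name="chr1", assembly_length=194_400_000, mean_sc_length=24.5)


@pytest.fixture
def toy_chrom() -> ChromosomeModel:
    return ChromosomeModel(name="toy", assembly_length=25_000_000, mean_sc_length=10.0)


@pytest.fixture
def toy_grid(toy_chrom):
    return build_interval_grid(toy_chrom, 2_500_000)


def make_focus_table(rows, n_cells=None) -> FocusTable:
    """rows: (cell_id, chromosome, sc_length_um, position, position_unit)."""
    data = pd.DataFrame(
        rows,
        columns=["cell_id", "chromosome", "sc_length_um", "position", "position_unit"],
    )
    return FocusTable(data=data, n_cells=n_cells or {})


@pytest.fixture
def simple_table() -> FocusTable:
    """10 cells, each with foci at fractions 0.1 and 0.9 on 'toy'."""
    rows = []
    for i in range(10):
        rows.append((f"c{i}", "toy", np.nan, 0.1, "fraction"))
        rows.append((f"c{i}", "toy", np.nan, 0.9, "fraction"))
    return make_focus_table(rows)


@pytest.fixture(scope="session")
def small_genome():
    """A shared two-chromosome simulated genome with planted structure."""
    params = GenomeSimParams(
        lengths=(800_000, 600_000),
        gc_baseline=0.45,
        gc_amplitude=0.05,
        cgi_rate=5.0,
        genes_per_Mb=20.0,
        coupling_rho=0.0,
        seed=11,
    )
    return simulate_genome(params, interval_size=100_000)
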