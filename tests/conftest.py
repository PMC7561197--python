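import numpy as np
import pandas as pd
import pytest

from ecadscreen.config import ScreenConfig
from ecadscreen.layouts import primary_layout


@pytest.fixture(scope="session")
def config() -> ScreenConfig:
    return ScreenConfig()


@pytest.fixture(scope="session")
def small_primary_layout():
    return primary_layout("P001", [f"GENE{i:03d}" for i in range(20)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_well_table(layout, ecad_by_role=None, count_by_role=None, plate_suffix=""):
    """Deterministic well table: every well gets role-dependent fixed values."""
    ecad_by_role = ecad_by_role or {}
    count_by_role = count_by_role or {}
    rows = []
    for well in sorted(layout.wells):
        spec = layout.wells[well]
        rows.append(
            {
                "plate_id": layout.plate_id + plate_suffix,
                "well": well,
                "role": spec.role,
                "gene_symbol": spec.gene_symbol,
                "duplex_index": spec.duplex_index,
                "cell_count": float(count_by_role.get(spec.role, 3000.0)),
                "fov_used": 20,
                "sparse_terminated": False,
                "ecad_raw": float(ecad_by_role.get(spec.role, 1.0)),
            }
        )
    return pd.DataFrame(rows)
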