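import numpy as np
import pandas as pd
import pytest

from phoscall import PhosphoSiteTable
from phoscall.tables import design_from_sample_names


def make_table(values: np.ndarray, samples: list[str],
               accessions=None, positions=None, residues=None,
               loc_probs=None) -> PhosphoSiteTable:
    """Build a small table with defaulted metadata for tests."""
    n = len(values)
    sites = pd.DataFrame({
        "accession": accessions or [f"P{i:05d}" for i in range(n)],
        "position": positions or list(range(10, 10 + 5 * n, 5)),
        "residue": residues or ["S"] * n,
        "localization_prob": loc_probs if loc_probs is not None else [0.99] * n,
        "multiplicity": 1,
    })
    return PhosphoSiteTable(
        sites=sites,
        values=pd.DataFrame(np.asarray(values, dtype=float), columns=samples),
        design=design_from_sample_names(samples),
    )


@pytest.fixture
def six_sample_names():
    return ["ctrl_1", "ctrl_2", "ctrl_3", "oa_1", "oa_2", "oa_3"]


@pytest.fixture
def small_table(six_sample_names):
    values = np.array([
        [20.0, 20.5, 19.5, 18.0, 18.2, 17.8],
        [25.0, 25.1, 24.9, 25.0, 25.2, 24.8],
        [22.0, np.nan, 21.8, 22.1, 22.0, np.nan],
    ])
    return make_table(values, six_sample_names)
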