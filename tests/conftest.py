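import numpy as np
import pandas as pd
import pytest

from synprot.design import Comparison, ComparisonDesign, default_study_design


@pytest.fixture(scope="session")
def study_design():
    return default_study_design()


@pytest.fixture
def two_pool_design():
    """Minimal one-comparison design for focused unit tests."""
    return ComparisonDesign(
        (Comparison("case_vs_ctrl", "pool_case", "pool_ctrl", "BA9", "ALS"),)
    )


@pytest.fixture
def make_table():
    """Factory for small hand-built quantification tables."""

    def _make(intensities: dict[str, list], peptides=None, accessions=None):
        n = len(next(iter(intensities.values())))
        acc = accessions or [f"P{i:05d}" for i in range(n)]
        df = pd.DataFrame(
            {
                "symbol": [f"G{i}" for i in range(n)],
                "unique_peptides": peptides if peptides is not None else [3] * n,
                **{k: np.asarray(v, dtype=float) for k, v in intensities.items()},
            },
            index=pd.Index(acc, name="accession"),
        )
        return df

    return _make
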