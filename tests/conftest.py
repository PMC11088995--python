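import numpy as np
import pandas as pd
import pytest

from quadromics import ExpressionMatrix, generate_cohort, simulate_cohort


@pytest.fixture(scope="session")
def design():
    return generate_cohort(n_per_cell=3, seed=1)


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared by read-only tests."""
    return simulate_cohort(seed=1)


@pytest.fixture
def make_lfq(design):
    """Build a small LFQ matrix over the standard design.

    ``fill`` callable maps (feature index, sample row) -> value or NaN.
    """

    def _make(n_features=4, fill=None, peptide_counts=None, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        rows = design.samples
        data = np.empty((n_features, len(rows)))
        for i in range(n_features):
            for j, (_, srow) in enumerate(rows.iterrows()):
                if fill is None:
                    data[i, j] = 2.0 ** rng.normal(25, 1)
                else:
                    data[i, j] = fill(i, srow)
        values = pd.DataFrame(
            data, index=[f"prot{i}" for i in range(n_features)],
            columns=design.sample_ids,
        )
        pep = pd.Series(
            peptide_counts if peptide_counts is not None else [3] * n_features,
            index=values.index,
        )
        return ExpressionMatrix(values, layer="LFQ", peptide_counts=pep)

    return _make
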