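import numpy as np
import pandas as pd
import pytest

from screenlink import io, synth


@pytest.fixture(scope="session")
def screens():
    """One deterministic joint screen with planted links, shared across tests."""
    return synth.generate_screens(
        n_genes=50, n_drugs=30, n_cells=200, n_links=5,
        effect=0.6, noise=0.6, missing_frac=0.1, seed=11,
    )


@pytest.fixture(scope="session")
def chem_panel():
    return synth.generate_chemistry(seed=0)


@pytest.fixture()
def toy_matrix():
    """3 genes x 4 cell lines with one missing value."""
    df = pd.DataFrame(
        [[-1.2, -0.5, np.nan, 0.3], [0.1, 0.2, 0.3, 0.4], [-2.0, -1.5, -1.1, -0.9]],
        index=["CDK6", "TP53", "BRAF"],
        columns=["L1", "L2", "L3", "L4"],
    )
    return io.DependencyMatrix(io.GENE_EFFECT, df)
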