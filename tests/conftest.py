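import numpy as np
import pandas as pd
import pytest

from sccmet.signature import ExpressionCohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_cohort():
    """Hand-built 4-gene, 9-sample cohort with known structure.

    GENE_UP is doubled in SCC; GENE_FLAT is constant; NC medians are simple
    round numbers so normalisation is checkable by hand.
    """
    samples = [f"S{i}" for i in range(9)]
    tissue = ["NC"] * 3 + ["AdC"] * 3 + ["SCC"] * 3
    matrix = pd.DataFrame(
        {
            "GENE_UP": [1.0, 2.0, 3.0, 2.0, 2.0, 2.0, 4.0, 4.0, 4.0],
            "GENE_FLAT": [5.0] * 9,
            "GENE_DOWN": [4.0, 4.0, 4.0, 4.0, 4.0, 4.0, 1.0, 1.0, 1.0],
            "GENE_NOISY": [1.0, 1.5, 2.0, 1.2, 1.8, 1.1, 1.4, 1.6, 1.3],
        },
        index=samples,
    ).T
    metadata = pd.DataFrame({"tissue": tissue, "subject_id": samples},
                            index=pd.Index(samples, name="sample_id"))
    return ExpressionCohort(matrix=matrix, metadata=metadata)
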