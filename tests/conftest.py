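import numpy as np
import pandas as pd
import pytest

from slscreen import CohortParams, generate_cohort
from slscreen.dataio import MutationCatalog, OmicsMatrix, Role, SampleAnnotation


@pytest.fixture
def small_cohort():
    """A 200-line cohort with one strongly planted SL pair."""
    return generate_cohort(CohortParams(seed=7))


@pytest.fixture
def tiny_matrix():
    data = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, np.nan]],
        index=["S1", "S2", "S3"],
        columns=["G1", "G2"],
    )
    return OmicsMatrix(data, Role.EXPRESSION)


@pytest.fixture
def tiny_mutations():
    return MutationCatalog(pd.DataFrame({
        "sample": ["S1", "S1", "S2"],
        "gene": ["G1", "G1", "G2"],
        "variant_classification": [
            "Missense_Mutation", "Missense_Mutation", "Silent",
        ],
    }))


@pytest.fixture
def tiny_annotation():
    return SampleAnnotation(
        pd.Series({"S1": "BRCA", "S2": "BRCA", "S3": "LUAD"})
    )
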