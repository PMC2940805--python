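import numpy as np
import pytest

from hapcarrier import (
    CohortDataset,
    GenotypeMatrix,
    VariantAnnotation,
    simulate_cohort,
)
from hapcarrier.synthetic_cohort import default_config


@pytest.fixture(scope="session")
def gene2_cohort():
    """Study-sized null cohort: 179 individuals, 11 carriers, 4 tag SNPs."""
    config = default_config(gene="gene2", seed=20260921)
    return simulate_cohort(config)


@pytest.fixture
def tiny_dataset():
    """Six individuals, one common and one deleterious variant."""
    matrix = GenotypeMatrix(
        individual_ids=[f"I{i}" for i in range(6)],
        variant_labels=["100 A > G", "200 del C"],
        dosages=np.array(
            [[0, 0], [1, 0], [2, 0], [1, 1], [0, 0], [np.nan, 0]], dtype=float
        ),
    )
    annotations = [
        VariantAnnotation(label="100 A > G", deleterious=False),
        VariantAnnotation(label="200 del C", deleterious=True),
    ]
    return CohortDataset.from_parts(matrix, annotations)
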