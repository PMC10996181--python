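import numpy as np
import pytest

from coexkit import ExpressionMatrix, SyntheticConfig, generate_dataset

# Six genes, five samples, crafted so that the computed pcc(g1,g3) and
# pcc(g2,g3) equal the 0.6 threshold exactly (in floating point) and the
# signed networks can be enumerated by hand (see test_acceptance).
SIX_GENES = {
    "g1": [3, 4, 6, 5, 7],
    "g2": [4, 5, 7, 6, 8],   # g1 + 1: identical deviations, so pcc(g2,g3)=0.6 too
    "g3": [2, 1, 3, 0, 4],
    "g4": [7, 6, 4, 5, 3],   # 10 - g1: perfect anti-correlation with g1
    "g5": [3, 5, 7, 4, 8],
    "g6": [8, 7, 2, 6, 1],
}


@pytest.fixture(scope="session")
def six_gene_expr() -> ExpressionMatrix:
    return ExpressionMatrix(
        gene_ids=list(SIX_GENES),
        sample_ids=["s1", "s2", "s3", "s4", "s5"],
        values=np.array(list(SIX_GENES.values()), dtype=float),
    )


@pytest.fixture(scope="session")
def study_bundle():
    """One default-condition synthetic bundle shared across read-only tests."""
    return generate_dataset(SyntheticConfig(seed=7))
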