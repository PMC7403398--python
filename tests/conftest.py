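import numpy as np
import pytest

from lethscan.io import GenotypeMatrix, VariantDef


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """4 samples x 3 variants with one missing call."""
    variants = [
        VariantDef("1", 100, "v1", "A", "G"),
        VariantDef("1", 200, "v2", "C", "T"),
        VariantDef("2", 50, "v3", "A", "C"),
    ]
    calls = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, -1],
            [1, 2, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        variants=variants,
        samples=["s1", "s2", "s3", "s4"],
        calls=calls,
        population={"s1": "popA", "s2": "popA", "s3": "popB", "s4": "popB"},
    )
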