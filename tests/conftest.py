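import numpy as np
import pytest

from otunet import OtuTable, SampleMetadata


@pytest.fixture
def toy_table() -> OtuTable:
    """3 OTUs x 4 samples with unequal depths."""
    counts = np.array(
        [[10, 0, 3, 7],
         [5, 12, 0, 1],
         [0, 8, 9, 2]]
    )
    return OtuTable(counts, ("OTU1", "OTU2", "OTU3"), ("S1", "S2", "S3", "S4"))


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    return SampleMetadata({"S1": "FP", "S2": "FP", "S3": "DI", "S4": "DI"})
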