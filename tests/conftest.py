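import numpy as np
import pandas as pd
import pytest

from mirpanel.containers import CqMatrix, validate_sample_metadata


@pytest.fixture
def two_group_meta():
    def make(d_ids, h_ids, **extra):
        rows = [
            {"sample_id": s, "group": "disease", "biofluid": "serum", **extra}
            for s in d_ids
        ] + [
            {"sample_id": s, "group": "healthy", "biofluid": "serum", **extra}
            for s in h_ids
        ]
        return validate_sample_metadata(pd.DataFrame(rows))

    return make


@pytest.fixture
def small_cq():
    values = pd.DataFrame(
        {
            "S1": [20.0, 30.0, 25.0],
            "S2": [21.0, 31.0, 26.0],
            "S3": [19.5, 29.5, 24.5],
        },
        index=["A", "B", "C"],
    )
    return CqMatrix(values)
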