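import numpy as np
import pandas as pd
import pytest

from kinmeta import ExpressionMatrix, SampleMetadata


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    data = pd.DataFrame(
        {
            "s1": [0.0, 1.2, -0.3],
            "s2": [1.5, -2.0, 0.1],
            "s3": [0.7, 0.4, np.nan],
            "s4": [-1.1, 0.9, 2.2],
        },
        index=["At1g01010", "At1g01020", "At1g01030"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def small_metadata() -> SampleMetadata:
    table = pd.DataFrame(
        {
            "experiment_id": ["E1", "E1", "E2", "E2"],
            "tissue": ["root", "root", "leaf", "leaf"],
            "dev_stage": ["seedling", "seedling", "rosette", "rosette"],
            "time_hours": [0.0, 3.0, np.nan, np.nan],
            "replicate_group": ["", "", "", ""],
            "treatment": ["cold", "cold", "drought", "drought"],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return SampleMetadata(table)


def make_metadata(tissues: dict[str, int], start: int = 0) -> SampleMetadata:
    """Metadata with `count` samples per tissue, one experiment per tissue."""
    rows = []
    i = start
    for tissue, count in tissues.items():
        for _ in range(count):
            rows.append(
                {
                    "sample_id": f"s{i:04d}",
                    "experiment_id": f"E_{tissue}",
                    "tissue": tissue,
                    "dev_stage": "",
                    "time_hours": np.nan,
                    "replicate_group": "",
                    "treatment": "",
                }
            )
            i += 1
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))
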