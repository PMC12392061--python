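import numpy as np
import pandas as pd
import pytest

from evmir.cq_io import SampleSheet
from evmir.datasets import synthetic_reference_dataset
from evmir.detection import detection_call, group_complete
from evmir.normalization import global_mean_normalize, normalizer_set
from evmir.signatures import build_catalog


@pytest.fixture(scope="session")
def reference():
    """The synthetic reference dataset with its full comparison catalog."""
    cq, sheet = synthetic_reference_dataset()
    det = group_complete(detection_call(cq), sheet)
    norm = global_mean_normalize(cq, det, normalizer_set(det))
    catalog = build_catalog(norm, det, sheet)
    return {"cq": cq, "sheet": sheet, "det": det, "norm": norm,
            "catalog": catalog}


def make_sheet(groups: dict[str, list[str]]) -> SampleSheet:
    """Sample sheet from {"FPP:IN": [sample ids], ...}."""
    rows = []
    for g, samples in groups.items():
        ct, comp = g.split(":")
        for i, s in enumerate(samples):
            rows.append({"sample_id": s, "donor": f"C{i + 1}",
                         "cell_type": ct, "compartment": comp})
    return SampleSheet(pd.DataFrame(rows))


def two_group_sheet(n: int = 3) -> SampleSheet:
    return make_sheet({
        "FPP:IN": [f"F{i}" for i in range(n)],
        "NSC:IN": [f"N{i}" for i in range(n)],
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
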