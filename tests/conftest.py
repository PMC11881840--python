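import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from jointomics import CohortDesign, FeatureTable, SampleMetadata, simulate

DATA = Path(__file__).parent / "data"
FIXTURE = DATA / "cohort_small"


@pytest.fixture(scope="session")
def fixture_dir() -> Path:
    return FIXTURE


@pytest.fixture(scope="session")
def fixture_truth() -> dict:
    with open(FIXTURE / "truth.json") as fh:
        return json.load(fh)


def small_design(**overrides) -> CohortDesign:
    """A fast cohort for unit tests: 3 groups x 3 mice x 5 timepoints."""
    kw = dict(
        mice_per_group=3,
        timepoints=tuple(np.linspace(10.0, 19.5, 5)),
        n_microbes=50,
        n_metabolites=60,
        depth_mean=2000.0,
        n_akkermansiaceae=5,
        n_muribaculaceae=7,
        n_pairs=3,
        n_group_metabolites=8,
    )
    kw.update(overrides)
    return CohortDesign(**kw)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate(small_design(), truth_seed=7)


@pytest.fixture
def toy_counts() -> FeatureTable:
    df = pd.DataFrame(
        [[5, 0, 3], [2, 7, 1], [0, 1, 9], [4, 4, 4]],
        index=["s1", "s2", "s3", "s4"],
        columns=["f1", "f2", "f3"],
    )
    return FeatureTable(df, kind="counts")


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    df = pd.DataFrame(
        {
            "host_subject_id": ["m1", "m1", "m2", "m2"],
            "host_age": [10.0, 12.0, 10.0, 12.0],
            "diet": ["RC", "RC", "HFHC", "HFHC"],
            "exposure": ["Air", "Air", "IHC", "IHC"],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return SampleMetadata(df)
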