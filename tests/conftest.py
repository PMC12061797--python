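import dataclasses

import pytest

import qsmflora as qf
from qsmflora import constants as C
from qsmflora.branch_data import records_to_frame, trees_to_frame
from qsmflora.synthetic import SyntheticForestSpec


@pytest.fixture(scope="session")
def truth_no_re():
    """Reference hurdle truth with random-intercept SDs switched off."""
    return dataclasses.replace(C.REFERENCE_HURDLE, sd_tree=0.0, sd_branch=0.0)


@pytest.fixture(scope="session")
def small_dataset(truth_no_re):
    spec = SyntheticForestSpec(n_trees=10, cutoffs_per_tree=8, hurdle=truth_no_re)
    records, trees, _ = qf.generate_branch_dataset(spec, seed=3)
    return records, trees


@pytest.fixture(scope="session")
def small_frames(small_dataset):
    records, trees = small_dataset
    return records_to_frame(records), trees_to_frame(trees)


@pytest.fixture(scope="session")
def fitted_fixed(small_frames):
    df, tdf = small_frames
    return qf.fit_hurdle(df, tdf)


@pytest.fixture(scope="session")
def demo_qsm():
    return qf.generate_qsm(20.0, seed=5)
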