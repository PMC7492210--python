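import numpy as np
import pytest

import tractnet as tn


@pytest.fixture(scope="session")
def small_parcellation() -> tn.LabelVolume:
    """Ten-ROI phantom on a 16^3 grid, identity affine."""
    return tn.make_phantom_parcellation(10, (16, 16, 16), seed=11)


@pytest.fixture(scope="session")
def small_subject(small_parcellation) -> tn.SubjectData:
    """One PD subject with a constant-FA field and a known tractogram."""
    fa = tn.make_phantom_fa(small_parcellation, 0.5, 0.0, seed=1)
    tract = tn.make_phantom_tractogram(
        small_parcellation, [(1, 2), (2, 3)], [3, 1], seed=2
    )
    return tn.SubjectData("pd000", "PD", small_parcellation, fa, tract, updrs_motor=18.4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
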