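import warnings

import numpy as np
import pytest
from hypothesis import settings

import tumortex as tx

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rois():
    """The deterministic micro-fixture ROIs."""
    return tx.fixture_rois()


@pytest.fixture(scope="session")
def random_roi():
    """A fully-masked 8x8 ROI with reproducible random intensities."""
    rng = np.random.default_rng(42)
    return tx.SliceROI(
        intensities=rng.uniform(20.0, 120.0, size=(8, 8)),
        mask=np.ones((8, 8), dtype=bool),
    )


@pytest.fixture(scope="session")
def study_cohort():
    """The default synthetic study cohort (20 short / 15 long survivors)."""
    return tx.generate_cohort(tx.SyntheticCohortSpec(seed=11))


@pytest.fixture(scope="session")
def study_table(study_cohort):
    """Feature table of the study cohort (extracted once per session)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tx.build_cohort_table(study_cohort)


@pytest.fixture()
def single_slice_tumor():
    """A square, fully-masked single-slice tumor for invariance checks."""
    rng = np.random.default_rng(7)
    img = rng.uniform(30.0, 110.0, size=(16, 16, 1))
    return tx.TumorVolume(
        intensities=img,
        mask=np.ones((16, 16, 1), dtype=bool),
        spacing=(0.7324, 0.7324, 2.5),
        label=0,
        patient_id="T0",
    )
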