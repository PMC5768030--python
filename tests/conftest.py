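import numpy as np
import pytest

import dwmetrics as dm


@pytest.fixture(scope="session")
def default_cohort():
    """The default seeded synthetic cohort (120 CAP + 80 chest)."""
    return dm.sample_cohort(dm.CohortConfig())


@pytest.fixture(scope="session")
def cap_records(default_cohort):
    return [r for r in default_cohort if r.exam_type == "CAP"]


@pytest.fixture
def disk_slice():
    """Factory: a single noise-free uniform disk slice."""

    def make(diameter_cm, pixel_spacing=0.8, image_size=512, hu=0.0):
        spec = dm.PhantomSpec(
            "disk", (diameter_cm,), uniform_hu=hu, pixel_spacing=pixel_spacing, image_size=image_size
        )
        return dm.make_phantom_series(spec, n_slices=1).slices[0]

    return make


@pytest.fixture
def small_series():
    """A 3-slice series with structured pixels and full metadata, for I/O tests."""
    rng = np.random.default_rng(42)
    slices = []
    for i, z in enumerate((0.0, 5.0, 10.0)):
        px = rng.integers(-1000, 1500, size=(32, 32)).astype(float)
        slices.append(
            dm.CTSlice(px, pixel_spacing=(0.8, 0.8), z_position=z, tube_current=100.0 + i, slice_id=i)
        )
    return dm.ScanSeries(
        slices=slices,
        ctdi_vol=10.5,
        exam_type="chest",
        scanner_id="CT14",
        patient=dm.PatientBio(weight=70.0, height=167.0, sex="F"),
    )
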