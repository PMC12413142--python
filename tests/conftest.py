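import numpy as np
import pytest

from ctcomp import PhantomSpec, SubjectRecord, gen_phantom


@pytest.fixture
def subject():
    return SubjectRecord(
        subject_id="s01", age_years=58.0, sex="female",
        height_cm=172.0, weight_kg=55.0,
    )


@pytest.fixture
def small_spec(subject):
    """A fast 96-px phantom with all four muscle classes populated."""
    return PhantomSpec(
        image_size=96,
        pixel_spacing_mm=1.5,
        body_axes_mm=(60.0, 50.0),
        muscle_ring=(25.0, 38.0),
        class_fractions=(0.6, 0.2, 0.1),
        vfat_target_cm2=8.0,
        sfat_target_cm2=10.0,
        subject=subject,
        seed=42,
    )


@pytest.fixture
def phantom_case(small_spec):
    return gen_phantom(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
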