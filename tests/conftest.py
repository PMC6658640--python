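import numpy as np
import pytest

import petharmony as ph


@pytest.fixture(scope="session")
def small_cohort():
    """Three synthetic studies under the three default settings (seeded)."""
    cfg = ph.CohortConfig(n_studies=3, seed=42)
    return ph.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_measurements(small_cohort):
    from petharmony.suv import measure_study

    return {
        s.study_id: measure_study(s.volumes, s.masks, s.meta)
        for s in small_cohort
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def sphere_phantom(diameter_mm=10.0, uptake=10.0, background=1.0, fov=61.0):
    """Single centered sphere on an odd 1 mm grid (a voxel center at 0)."""
    organ = ph.Organ("lesion", "sphere", (0, 0, 0),
                     (diameter_mm,) * 3, uptake, index=1)
    return ph.PhantomSpec((fov, fov, fov), [organ], background_uptake=background)
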