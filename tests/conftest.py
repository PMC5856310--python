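import numpy as np
import pytest

from srsqa.core import DoseGrid, Structure
from srsqa.synthetic import (
    LesionSpec,
    SyntheticPatientSpec,
    TechniqueProfile,
    build_structures,
    default_profiles,
    render_dose,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_grid_and_mask(rng, shape=(8, 8, 8), n_mask=30, spacing=(2.0, 2.0, 2.0),
                         dose_scale=20.0):
    """A random dose grid plus a random mask of exactly ``n_mask`` voxels."""
    values = rng.uniform(0.0, dose_scale, size=shape)
    flat = rng.choice(np.prod(shape), size=n_mask, replace=False)
    mask = np.zeros(np.prod(shape), dtype=bool)
    mask[flat] = True
    grid = DoseGrid(values, spacing)
    structure = Structure("s", "oar", mask.reshape(shape))
    return grid, structure


def uniform_structure(dose, n_vox=5, shape=(4, 4, 4), spacing=(1.0, 1.0, 1.0)):
    values = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    mask.flat[:n_vox] = True
    values[mask] = dose
    return DoseGrid(values, spacing), Structure("u", "oar", mask)


#: Three well-separated lesions, used whenever a deterministic patient is
#: needed; the third sits far from the first two so each is effectively
#: isolated for kernel-shape checks.
FIXED_LESIONS = [
    LesionSpec(center=(0.0, 0.0, -30.0), radius=8.0, prescription=18.0),
    LesionSpec(center=(0.0, 0.0, 30.0), radius=6.0, prescription=18.0),
    LesionSpec(center=(30.0, -30.0, 0.0), radius=7.0, prescription=18.0),
]


@pytest.fixture(scope="session")
def fixed_patient():
    return SyntheticPatientSpec(patient_id="fixed", lesions=list(FIXED_LESIONS), seed=7)


@pytest.fixture(scope="session")
def fixed_patient_prebuilt(fixed_patient):
    return build_structures(fixed_patient)


@pytest.fixture(scope="session")
def rendered_plan(fixed_patient, fixed_patient_prebuilt):
    """One normalized HA-like plan for the fixed three-lesion patient."""
    grid, structures = render_dose(
        fixed_patient, default_profiles()["HA-like"], prebuilt=fixed_patient_prebuilt
    )
    return grid, structures


def quiet_profile(**overrides):
    """A noise- and bath-free profile for deterministic kernel checks."""
    params = dict(
        name="quiet", falloff_length=4.0, bath_level=0.0,
        intra_target_heterogeneity=0.1, bridging_gain=0.0, noise_sd=0.0,
    )
    params.update(overrides)
    return TechniqueProfile(**params)
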