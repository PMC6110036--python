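import numpy as np
import pytest

from vesselmorph import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_groups():
    """Three small groups with graded hyperplasia for fast pipeline tests."""
    return (
        synthetic.GroupSpec(
            label="Normal",
            n_animals=3,
            lumen_radius_mean=250.0,
            intima_thickness_mean=0.0,
            media_thickness_mean=60.0,
            cv=0.05,
            expression_effects={"PCNA": 1.0},
        ),
        synthetic.GroupSpec(
            label="Model",
            n_animals=3,
            lumen_radius_mean=250.0,
            intima_thickness_mean=74.0,
            media_thickness_mean=60.0,
            eccentricity=0.3,
            cv=0.05,
            expression_effects={"PCNA": 2.0},
        ),
        synthetic.GroupSpec(
            label="Treated",
            n_animals=3,
            lumen_radius_mean=250.0,
            intima_thickness_mean=20.0,
            media_thickness_mean=60.0,
            eccentricity=0.3,
            cv=0.05,
            expression_effects={"PCNA": 1.3},
        ),
    )


@pytest.fixture
def tiny_cohort(tiny_groups):
    return synthetic.CohortConfig(
        groups=tiny_groups, slices_per_vessel=2, fields_per_slice=3, seed=7
    )
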