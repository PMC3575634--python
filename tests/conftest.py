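"""Shared geometric fixtures.

Everything is generated programmatically; the analytic cylinder scaffolds
(concentric and offset nail-in-canal) have closed-form penetration values
used as oracles throughout the suite.
"""

import numpy as np
import pytest

from femfit.metrics import FitnessOptions, penetration_field
from femfit.nails import build_nail_mesh, make_generic_spec, make_pfna2_spec
from femfit.placement import PlacementResult
from femfit.synthetic import (PopulationSpec, build_femur, cylinder_canal,
                              sample_population)
from femfit.transforms import RigidTransform


def manual_placement(translation, entry=None, tip_offset=None,
                     rotation=np.eye(3)):
    """PlacementResult for a hand-constructed pose (analytic scaffolds)."""
    t = np.asarray(translation, float)
    return PlacementResult(
        transform=RigidTransform(rotation, t),
        entry_point=np.array([t[0], t[1], 0.0]) if entry is None else np.asarray(entry, float),
        insertion_depth=0.0,
        tip_offset=float(t[2]) if tip_offset is None else tip_offset,
        rotation_deg=0.0, head_center_miss=0.0, converged=True)


@pytest.fixture(scope="session")
def canal6():
    """Straight cylindrical canal, radius 6 mm, length 120 mm, apex at the
    top cap center (canal axis = z axis)."""
    return cylinder_canal(6.0, 120.0)


@pytest.fixture(scope="session")
def nail80():
    """Straight circular nail, radius 5 mm, length 80 mm."""
    return build_nail_mesh(make_generic_spec(80.0, 10.0))


@pytest.fixture(scope="session")
def concentric_field(canal6, nail80):
    """Nail coaxial in the canal, fully inside: every depth is −1 mm."""
    pl = manual_placement([0.0, 0.0, 20.0])
    return penetration_field(canal6, nail80, pl), pl


@pytest.fixture(scope="session")
def offset_field(canal6, nail80):
    """Nail axis offset 2 mm laterally: max depth = 2 + 5 − 6 = 1 mm."""
    pl = manual_placement([2.0, 0.0, 20.0])
    return penetration_field(canal6, nail80, pl), pl


@pytest.fixture(scope="session")
def cohort_params():
    return sample_population(PopulationSpec(n=4, seed=11))


@pytest.fixture(scope="session")
def femur_seeded(cohort_params):
    """One realistic bowed synthetic femur (seed 11, first draw)."""
    return build_femur(cohort_params[0], "f_seeded")


@pytest.fixture(scope="session")
def pfna2_nail():
    return build_nail_mesh(make_pfna2_spec(170.0, 10.0))


@pytest.fixture(scope="session")
def fast_fitness_opts():
    """Reduced sample density to keep the suite quick; analytic tolerances
    in the tests account for it."""
    return FitnessOptions(density=2.0, allow_unconverged=True)
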