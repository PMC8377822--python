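import numpy as np
import pytest

from rvflow.fields import Landmarks, SegmentationMask
from rvflow.phantom import GridSpec, PhantomSpec, make_analytic_field, make_rv_phantom


@pytest.fixture(scope="session")
def rigid_rotation():
    """Rigid rotation about z at 5 rad/s inside a ~10 mL sphere, 1 mm voxels."""
    grid = GridSpec(shape=(34, 34, 34), spacing=1.0, n_phases=2)
    fld, mask, truth = make_analytic_field(
        "rigid_rotation", {"omega_rad_s": 5.0, "radius_mm": 13.37}, grid)
    return fld, mask, truth


@pytest.fixture(scope="session")
def poiseuille_1mm():
    grid = GridSpec(shape=(56, 24, 24), spacing=1.0, n_phases=2)
    return make_analytic_field(
        "poiseuille", {"U": 1.0, "R_mm": 10.0, "L_mm": 50.0}, grid)


@pytest.fixture(scope="session")
def rv_phantom_s05():
    """Mid-severity RV phantom, noise-free (shared across read-only tests)."""
    return make_rv_phantom(PhantomSpec(pr_severity=0.5))


@pytest.fixture()
def cuboid_fixture():
    """20x20x40-voxel cuboid RV at 1 mm with the standard two-plane landmarks:
    cut 1 at z = 30 (normal +z, pulmonary valve above), cut 2 at z = 15."""
    labels = np.zeros((40, 20, 20), dtype=np.int32)
    labels[:, :, :] = 1
    mask = SegmentationMask(labels=labels, label_names={1: "RV"},
                            spacing=np.array([1.0, 1.0, 1.0]))
    lm = Landmarks(
        commissure_point=np.array([10.0, 10.0, 30.0]),
        four_chamber_normal=np.array([0.0, 0.0, 1.0]),
        tricuspid_centroid=np.array([10.0, 10.0, 30.0]),
        apex_point=np.array([10.0, 10.0, 0.0]),
        pv_centroid=np.array([10.0, 10.0, 35.0]),
    )
    return mask, lm
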