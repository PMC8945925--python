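import numpy as np
import pytest

from metpet import (
    LesionSpec,
    LesionVOI,
    LiverRegionSpec,
    PhantomSpec,
    make_phantom,
)


def lesion(id="L", sul_max=5.0, sul_mean=None, mtv=1.0, organ=1,
           centroid=(0.0, 0.0, 0.0)) -> LesionVOI:
    """Hand-built lesion for selection/matching tests."""
    sm = sul_max if sul_mean is None else sul_mean
    return LesionVOI(
        id=id, organ_label=organ, sul_max=sul_max, sul_mean=sm,
        mtv_cm3=mtv, tlg_g=sm * mtv, centroid_mm=tuple(map(float, centroid)),
        n_voxels=max(1, int(round(mtv * 125))),
    )


@pytest.fixture
def sphere_phantom_spec() -> PhantomSpec:
    """Noiseless phantom: one 10-mm-radius plateau sphere (SUL 8) plus a
    liver reference region, on a 2-mm grid."""
    return PhantomSpec(
        grid_shape=(60, 60, 60),
        voxel_spacing_mm=(2.0, 2.0, 2.0),
        background_sul=0.5,
        noise_sd=0.0,
        liver_region=LiverRegionSpec(center_mm=(30.0, 30.0, 30.0),
                                     radius_mm=25.0, mean_sul=2.0, sd_sul=0.0),
        lesions=(LesionSpec(center_mm=(80.0, 80.0, 80.0),
                            radii_mm=(10.0, 10.0, 10.0),
                            peak_sul=8.0, organ_label=5, id="T1"),),
        rng_seed=11,
    )


@pytest.fixture
def sphere_phantom(sphere_phantom_spec):
    return make_phantom(sphere_phantom_spec)
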