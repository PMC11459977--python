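import numpy as np
import pytest

from pinspect.geometry import CollimatorParams, DetectorParams, HoleSpec, OrbitSpec
from pinspect.io_interfile import ImageVolume
from pinspect.system_matrix import BinGrid, MatrixConfig, PinholeProjector


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    """Compile the numba kernels once up front so timings stay predictable."""
    from pinspect._kernels import warmup

    warmup()


def make_hole(diameter=1.0, distance=24.0, acceptance=50.0, **kw):
    return HoleSpec(position=(0.0, distance, 0.0), size=diameter,
                    acceptance_angle=acceptance, **kw)


def make_detector(orbit, resolution=1.8, thickness=6.0, mu_c=0.25, face=57.0):
    return DetectorParams(
        intrinsic_resolution=resolution,
        crystal_thickness=thickness,
        crystal_attenuation=mu_c,
        detector_radius=face,
        orbit=orbit,
    )


@pytest.fixture(scope="session")
def fixture_problem():
    """Small end-to-end problem: 16^3 grid, 8 views, 24x24 bins."""
    orbit = OrbitSpec(n_angles=8, initial_angle=180.0, angular_increment=33.75)
    detector = make_detector(orbit)
    collimator = CollimatorParams(radius_of_rotation=24.0, holes=[make_hole()])
    grid = ImageVolume(np.zeros((16, 16, 16)), voxel_size=1.5)
    bins = BinGrid(n_axial=24, n_trans=24, bin_size=1.5)
    return dict(orbit=orbit, detector=detector, collimator=collimator,
                grid=grid, bins=bins)


def make_projector(problem, atten_map=None, **config_kw):
    config = MatrixConfig(**config_kw)
    return PinholeProjector(
        problem["grid"], problem["detector"], problem["collimator"],
        config, problem["bins"], atten_map=atten_map,
    )
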