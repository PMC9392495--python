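import pytest

from vsrdv.acquisition import EncodingScheme, coil_sensitivities
from vsrdv.phantom import (PhantomConfig, PlaneSpec, StraightCenterline,
                           VesselSpec, make_phantom)


def tiny_phantom_config(fast_speed: float = 80.0,
                        slow_speed: float = 40.0) -> PhantomConfig:
    """Two straight tubes on a 32x32x16 grid; peaks straddle venc_low=55."""
    return PhantomConfig(
        shape=(32, 32, 16), voxel_size_mm=1.0, n_frames=6,
        vessels=[
            VesselSpec("FAST", StraightCenterline((16.0, 10.0, 2.0),
                                                  (16.0, 10.0, 13.0)),
                       radius_mm=3.0, peak_centerline_speed=fast_speed),
            VesselSpec("SLOW", StraightCenterline((16.0, 22.0, 2.0),
                                                  (16.0, 22.0, 13.0)),
                       radius_mm=2.5, peak_centerline_speed=slow_speed),
        ],
        planes=[
            PlaneSpec((16.0, 10.0, 5.0), (0.0, 0.0, 1.0), 12.0, "FAST"),
            PlaneSpec((16.0, 10.0, 9.0), (0.0, 0.0, 1.0), 12.0, "FAST"),
            PlaneSpec((16.0, 22.0, 5.0), (0.0, 0.0, 1.0), 10.0, "SLOW"),
            PlaneSpec((16.0, 22.0, 9.0), (0.0, 0.0, 1.0), 10.0, "SLOW"),
        ],
    )


@pytest.fixture(scope="session")
def tiny_phantom():
    return make_phantom(tiny_phantom_config(), seed=3)


@pytest.fixture(scope="session")
def scheme():
    return EncodingScheme(55.0, 110.0)


@pytest.fixture(scope="session")
def sens8(tiny_phantom):
    return coil_sensitivities(8, tiny_phantom.config.shape, seed=5)
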