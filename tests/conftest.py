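import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "dermoscan",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("dermoscan")


def disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Brute-force rasterized disc (pixel-center inclusion)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - center[1]) ** 2 + (yy - center[0]) ** 2 <= radius**2


@pytest.fixture(scope="session")
def clean_disc_sample():
    """Noiseless, sharp, high-contrast disc lesion: the easiest segmentation target."""
    from dermoscan.fixtures import LesionSpec, generate_lesion_image

    spec = LesionSpec(
        center=(128, 128),
        axes=(40, 40),
        boundary_wobble=0.0,
        texture_noise_sd=0.0,
        skin_noise_sd=0.0,
        border_softness=0.0,
        lesion_color=(50, 50, 50),
        skin_color=(200, 200, 200),
    )
    return generate_lesion_image(spec, 256, 256, seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """A small mixed dataset shared by feature/classifier sanity tests."""
    from dermoscan.fixtures import generate_dataset

    return generate_dataset(25, 25, seed=202)


@pytest.fixture(scope="session")
def roundness_dataset():
    """The 200-sample dataset used for class-separability checks."""
    from dermoscan.fixtures import generate_dataset

    return generate_dataset(100, 100, seed=7)
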