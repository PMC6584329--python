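import numpy as np
import pytest

import cortiq as cq


def zero_density(s):
    return np.zeros_like(np.asarray(s, float))


def uniform_density(level):
    return lambda s: np.full_like(np.asarray(s, float), float(level))


@pytest.fixture(scope="session")
def small_geometry():
    """Embryo that fits a 256x256 frame with the required margin."""
    return cq.EmbryoGeometry(center=(128, 128), semi_axes=(90, 60))


@pytest.fixture(scope="session")
def noise_free(small_geometry):
    """Noise-free cytoplasm-only frame plus its contour."""
    truth = cq.SyntheticGroundTruth(membrane_density=zero_density,
                                    gaussian_sd=0, poisson_gain=0)
    image, contour, record = cq.generate_frame(small_geometry, truth, (256, 256))
    return image, contour, record


@pytest.fixture(scope="session")
def reference(noise_free):
    """Cytoplasmic reference collapsed from the noise-free embryo's
    per-position profiles (the same population the fits are applied to)."""
    image, contour, _ = noise_free
    st = cq.straighten_cortex(image, contour)
    st = cq.rolling_average_along_cortex(st, 50)
    st = cq.smooth_straightened(st)
    return cq.derive_reference_profile(st.values,
                                       provenance="noise-free synthetic embryo")


def mean_cortex_profile(image, contour, rolling=50):
    st = cq.straighten_cortex(image, contour)
    st = cq.rolling_average_along_cortex(st, rolling)
    st = cq.smooth_straightened(st)
    return st.values.mean(axis=0)


@pytest.fixture(scope="session")
def analytic_reference():
    """Reference built from an analytic core+halo edge-spread curve."""
    from scipy.stats import norm

    j = np.arange(50, dtype=float)
    c = 24.5
    edge = 0.75 * norm.cdf((j - c) / 1.5) + 0.25 * norm.cdf((j - c) / 6.0)
    profile = 10.0 + 90.0 * edge
    return cq.derive_reference_profile(profile[None, :], provenance="analytic")
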