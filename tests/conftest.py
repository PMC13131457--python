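import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from evquant.imaging import BinaryMask, LabelMask, extract_particles  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def particles_from_labels(labels: np.ndarray, pixel_size_nm: float = 65.0,
                          intensity: np.ndarray | None = None):
    """Build a ParticleSet straight from an integer label raster."""
    lab = LabelMask(np.asarray(labels, dtype=np.int32), pixel_size_nm)
    inten = intensity if intensity is not None else np.ones(lab.shape)
    return extract_particles(lab, inten)


def random_sparse_particles(rng, shape=(64, 64), n=8, pixel_size_nm=65.0):
    """n single-pixel-to-small particles at random non-colliding positions."""
    labels = np.zeros(shape, dtype=np.int32)
    k = 0
    guard = 0
    while k < n:
        guard += 1
        assert guard < 10000
        r = int(rng.integers(1, shape[0] - 1))
        c = int(rng.integers(1, shape[1] - 1))
        if labels[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2].any():
            continue
        k += 1
        labels[r, c] = k
        if rng.random() < 0.5:  # sometimes a 2-pixel particle
            labels[r, c + 1] = k
    return particles_from_labels(labels, pixel_size_nm), labels


def brute_force_edge_nm(particle_coords, organelle_mask, pixel_size_nm):
    """All-pairs oracle for the edge-distance/contact rule."""
    import math

    org = np.argwhere(organelle_mask)
    d = np.sqrt(
        ((particle_coords[:, None, :] - org[None, :, :]) ** 2).sum(axis=2)
    ).min()
    if d <= math.sqrt(2) + 1e-9:
        return 0.0
    return (d - 1.0) * pixel_size_nm
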