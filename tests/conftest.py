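import numpy as np
import pytest

import shellbmd as sb


@pytest.fixture(scope="session")
def basis():
    return sb.default_basis()


@pytest.fixture(scope="session")
def phantom_spec():
    return sb.default_phantom_spec()


@pytest.fixture(scope="session")
def noise_free_phantom(phantom_spec, basis):
    """Noise-free phantom pair + truth, shared across tests (read-only)."""
    return sb.build_phantom_pair(phantom_spec, basis, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def calibration_model(noise_free_phantom, phantom_spec):
    v50, v200, _ = noise_free_phantom
    samples = sb.measure_insert_vois(v50, v200, phantom_spec)
    return sb.fit_calibration(samples)


@pytest.fixture(scope="session")
def fitted_distributions():
    return sb.default_distributions()


def brute_force_point_in_polygon(px: float, py: float, vertices) -> bool:
    """Even-odd ray-crossing oracle, independent of the shapely path."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def star_polygon(rng: np.random.Generator, n_vertices: int, radius: float, center=(0.0, 0.0)):
    """A random simple (star-shaped) polygon around `center`."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.3 * radius, radius, n_vertices)
    cx, cy = center
    return [(cx + r * np.cos(a), cy + r * np.sin(a)) for r, a in zip(radii, angles)]
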