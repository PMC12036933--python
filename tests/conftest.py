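import numpy as np
import pytest

from somamorph.geometry import Contour, normalize_contour


def random_star_polygon(rng: np.random.Generator, n_max: int = 50) -> Contour:
    """A random simple polygon: distinct sorted angles with random radii
    around the origin (star-shaped, hence simple)."""
    while True:
        n = int(rng.integers(5, n_max + 1))
        theta = np.sort(rng.uniform(0.0, 2.0 * np.pi, n))
        if np.min(np.diff(theta)) < 1e-4:
            continue
        r = rng.uniform(0.5, 2.0, n)
        v = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        try:
            return normalize_contour(v)
        except Exception:
            continue


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study with the reported effect directions,
    shared across pipeline/io/cli tests."""
    from somamorph.simulate import gen_study, reported_direction_effects

    return gen_study(n_statin=3, n_control=3, effects=reported_direction_effects(), seed=7)
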