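import numpy as np
import pytest

from chapsta import phantoms as ph
from chapsta.volumes import Volume, bandpass_filter


def masked_corr(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation restricted to a boolean mask."""
    x = a[mask].astype(np.float64)
    y = b[mask].astype(np.float64)
    x -= x.mean()
    y -= y.mean()
    return float((x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum()))


def central_sphere(box: int, radius: float) -> np.ndarray:
    c = box // 2
    zz, yy, xx = np.meshgrid(*([np.arange(box) - c] * 3), indexing="ij")
    return np.sqrt(zz**2 + yy**2 + xx**2) <= radius


@pytest.fixture(scope="session")
def geom():
    return ph.SpeciesGeometry()


@pytest.fixture(scope="session")
def bullet_map(geom):
    return ph.build_species_map(geom, ph.BULLET_WIDE, 48, 7.04)


@pytest.fixture(scope="session")
def smooth_bullet(bullet_map):
    """Low-passed phantom: smooth enough for interpolation round-trips."""
    return bandpass_filter(bullet_map, high_res=25.0)


@pytest.fixture(scope="session")
def football_map(geom):
    return ph.build_species_map(geom, ph.FOOTBALL, 48, 7.04)
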