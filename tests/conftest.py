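import numpy as np
import pytest

from npscreen import SimulationConfig


@pytest.fixture
def clean_config() -> SimulationConfig:
    """Noise-free, background-free generator: planted quantities are exact."""
    return SimulationConfig(
        noise_gaussian_sd=0.0, noise_poisson=False,
        background_gradient_amplitude=0.0,
    )


@pytest.fixture
def small_clean_config() -> SimulationConfig:
    """Tiny noise-free field for fast unit tests."""
    return SimulationConfig(
        field_shape=(128, 128), n_cells_per_field=6,
        noise_gaussian_sd=0.0, noise_poisson=False,
        background_gradient_amplitude=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160704)


# ---------------------------------------------------------------------------
# independent oracles (brute-force / enumeration; used only as references)


def disk_offsets(radius: int):
    offs = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dy * dy + dx * dx <= radius * radius:
                offs.append((dy, dx))
    return offs


def opening_subtract_oracle(image: np.ndarray, radius: int) -> np.ndarray:
    """Background subtraction by explicit Minkowski erosion/dilation with a
    disk: min over the footprint, then max, enumerated offset by offset."""
    image = np.asarray(image, float)
    h, w = image.shape
    offs = disk_offsets(radius)
    pad = radius
    big = np.pad(image, pad, constant_values=np.inf)
    ero = np.full((h, w), np.inf)
    for dy, dx in offs:
        ero = np.minimum(ero, big[pad + dy:pad + dy + h, pad + dx:pad + dx + w])
    big = np.pad(ero, pad, constant_values=-np.inf)
    bg = np.full((h, w), -np.inf)
    for dy, dx in offs:
        bg = np.maximum(bg, big[pad + dy:pad + dy + h, pad + dx:pad + dx + w])
    return np.clip(image - bg, 0.0, None)


def rwc_bruteforce(x, y, tx, ty) -> float:
    """Rank Weighted Colocalization by explicit enumeration: average ranks
    computed by counting, weights and sums accumulated in plain loops."""
    x = [float(v) for v in np.asarray(x).ravel()]
    y = [float(v) for v in np.asarray(y).ravel()]
    n = len(x)

    def rank_desc(vals, i):
        greater = sum(1 for v in vals if v > vals[i])
        equal = sum(1 for v in vals if v == vals[i])
        return greater + (equal + 1) / 2.0

    denom = sum(xi for xi in x if xi > tx)
    if n == 0 or denom <= 0:
        return 0.0
    num = 0.0
    any_coloc = False
    for i in range(n):
        if x[i] > tx and y[i] > ty:
            any_coloc = True
            d = abs(rank_desc(x, i) - rank_desc(y, i))
            num += x[i] * (n - d) / n
    return num / denom if any_coloc else 0.0
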