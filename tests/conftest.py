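import numpy as np
import pytest

from regmap.core_tracks import BaseTrack, WindowGrid, WindowTrack, tile_genome
from regmap.motif_scoring import build_pwm, train_background


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_grid():
    return tile_genome({"chr1": 3000, "chr2": 2000}, window_length=500, stride=50)


@pytest.fixture(scope="session")
def uniform_bg():
    """Order-0 strand-symmetric background."""
    return train_background(["ACGT" * 200], order=0, pseudocount=0.5)


@pytest.fixture(scope="session")
def order1_bg():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return train_background([seq], order=1, pseudocount=0.5)


@pytest.fixture(scope="session")
def sharp_pwm():
    """Width-6 PWM with a strong consensus ACGGTA."""
    counts = np.zeros((4, 6))
    for j, b in enumerate([0, 1, 2, 2, 3, 0]):
        counts[b, j] = 30
    return build_pwm(counts, pseudocount=0.5, motif_id="sharp")


def random_track(grid: WindowGrid, rng, low=0.0, high=10.0) -> WindowTrack:
    return WindowTrack(grid, rng.uniform(low, high, size=grid.n_windows))
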