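import numpy as np
import pytest

from dendrobomb.synth import BombCurveParams, synthetic_bomb_curve
from dendrobomb.types import RingWidthSeries


@pytest.fixture(scope="session")
def bomb_curve():
    return synthetic_bomb_curve(BombCurveParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_noise_series(rng, sid="NOI01A", first_year=1900, n=100, mean=1.0, sd=0.2):
    """Positive white-noise ring-width series."""
    w = np.clip(mean + sd * rng.standard_normal(n), 0.05, None)
    return RingWidthSeries(sid, first_year, tuple(w))


def make_common_signal_series(
    rng, n_series=6, n=120, first_year=1890, pair_r=0.5, scale=0.25
):
    """Series sharing a common signal with population pairwise correlation."""
    common = rng.standard_normal(n)
    out = []
    for i in range(n_series):
        noise = rng.standard_normal(n)
        z = np.sqrt(pair_r) * common + np.sqrt(1 - pair_r) * noise
        w = np.clip(1.0 + scale * z, 0.05, None)
        out.append(RingWidthSeries(f"SIG{i + 1:02d}", first_year, tuple(w)))
    return out
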