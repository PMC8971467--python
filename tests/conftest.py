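import numpy as np
import pytest

from yieldforge.data_io import StationMeta, YieldPanel


def make_panel(values, year_start=2000, ids=None):
    """Build a small panel from a 2-D array of yields."""
    values = np.asarray(values, dtype=float)
    n, T = values.shape
    ids = ids or [f"s{i}" for i in range(n)]
    return YieldPanel(
        stations=[StationMeta(station_id=i) for i in ids],
        years=np.arange(year_start, year_start + T),
        values=values,
    )


@pytest.fixture
def tiny_panel():
    """2 stations x 3 years, no gaps."""
    return make_panel([[10.0, 20.0, 30.0], [40.0, 50.0, 60.0]])


def ar1_series(rng, n, phi, mean=2000.0, std=400.0):
    z = np.empty(n)
    z[0] = rng.standard_normal()
    for t in range(1, n):
        z[t] = phi * z[t - 1] + np.sqrt(1 - phi**2) * rng.standard_normal()
    return mean + std * z


def wrapper_toy_panel(seed=0, n_years=40, n_good=3, n_noise=3, noise_sd=60.0):
    """Target plus candidates: noisy copies of the target and pure noise.

    The informative candidates track the target closely, so the cheapest
    wrapper subset is (almost surely uniquely) the set of copies.
    """
    rng = np.random.default_rng(seed)
    target = ar1_series(rng, n_years, phi=0.8)
    rows = [target]
    ids = ["target"]
    for i in range(n_good):
        rows.append(target + noise_sd * rng.standard_normal(n_years))
        ids.append(f"good{i}")
    for i in range(n_noise):
        rows.append(ar1_series(rng, n_years, phi=0.0, mean=2000.0, std=400.0))
        ids.append(f"noise{i}")
    return make_panel(np.vstack(rows), ids=ids)
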