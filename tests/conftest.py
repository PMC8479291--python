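import numpy as np
import pytest
from hypothesis import settings

from nuctrans.synthetic import SyntheticPopulationSpec, generate_population

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def default_spec():
    return SyntheticPopulationSpec(n_events=5, seed=7)


@pytest.fixture
def noise_free_spec():
    return SyntheticPopulationSpec(
        n_events=5, noise_sd=0.0, background_level=0.0, seed=7
    )


@pytest.fixture(scope="session")
def dose_populations():
    """Five populations sweeping the nuclear-fraction mean, scored lazily."""
    specs = {
        f: SyntheticPopulationSpec(
            n_events=200,
            nuclear_fraction_mean=f,
            nuclear_fraction_sd=0.05,
            group_label=f"frac{f}",
            seed=100 + i,
        )
        for i, f in enumerate([0.0, 0.25, 0.5, 0.75, 1.0])
    }
    return {f: generate_population(spec) for f, spec in specs.items()}


def brute_force_pearson(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Independent loop-based Pearson correlation over masked pixels."""
    xs, ys = [], []
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j]:
                xs.append(float(a[i, j]))
                ys.append(float(b[i, j]))
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    return cov / (vx**0.5 * vy**0.5)
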