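import numpy as np
import pytest

from incoscat.eins import EinsCurve


@pytest.fixture
def q_grid():
    """Instrument-like momentum-transfer grid, 0.2-4.9 1/A."""
    return np.linspace(0.2, 4.9, 30)


def make_curve(q, model, noise=0.0, seed=0, temperature=300.0):
    """Curve from a model vector with counting-statistics noise.

    noise = 0 gives the exact model with unit weights.
    """
    model = np.asarray(model, dtype=float)
    if noise == 0.0:
        return EinsCurve(q, model, np.ones_like(model), temperature)
    rng = np.random.default_rng(seed)
    sigma = noise * np.sqrt(model)
    return EinsCurve(q, model + rng.normal(size=model.size) * sigma, sigma,
                     temperature)
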