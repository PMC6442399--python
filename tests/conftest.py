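import numpy as np
import pytest

import botanitox as bt


@pytest.fixture
def curve_factory():
    """Build a ResponseCurve from a response vector (unit log10 spacing by default)."""

    def make(
        responses,
        logc=None,
        direction="increase",
        substance_id="s1",
        endpoint_id="ep01",
        run_index=1,
    ):
        responses = np.asarray(responses, dtype=float)
        if logc is None:
            logc = np.arange(responses.size, dtype=float)
        return bt.ResponseCurve(
            substance_id=substance_id,
            endpoint_id=endpoint_id,
            run_index=run_index,
            log10_concentration=np.asarray(logc, dtype=float),
            response=responses,
            direction=direction,
        )

    return make


@pytest.fixture
def threshold20():
    return bt.NoiseThreshold("ep01", 20.0, 5.0, 3.0, 10.0)


@pytest.fixture
def small_design():
    """A compact but structurally complete study: groups, lots, constituents."""
    return bt.SimulationDesign(
        n_groups=4,
        lots_per_group=3,
        constituents_per_group=1,
        n_endpoints=4,
        runs=3,
        noise_sd=5.0,
        seed=5,
    )


def random_filtered_curve(rng, n_points=None):
    """A random curve passed through the noise filter (for oracle checks)."""
    from botanitox import curvep

    n = n_points or rng.integers(4, 16)
    logc = np.sort(rng.uniform(-3, 3, n))
    while np.any(np.diff(logc) <= 0):
        logc = np.sort(rng.uniform(-3, 3, n))
    resp = rng.normal(0, 40, n)
    direction = "decrease" if rng.random() < 0.5 else "increase"
    curve = bt.ResponseCurve("s", "e", 1, logc, resp, direction)
    t = bt.NoiseThreshold("e", float(rng.uniform(5, 30)), 5.0, 3.0, 5.0)
    return curvep.filter_curve(curve, t), t
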