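import numpy as np
import pytest

from dermoct.features import GaborBank
from dermoct.synthetic import Layer, PhantomSpec, benign_spec, melanoma_spec, render


@pytest.fixture(scope="session")
def small_bank() -> GaborBank:
    """A 2x2 bank, enough structure for feature tests at low cost."""
    return GaborBank(frequencies=(0.1, 0.25), orientations=(0.0, np.pi / 2))


@pytest.fixture(scope="session")
def benign_phantom():
    return render(benign_spec(seed=11))


@pytest.fixture(scope="session")
def melanoma_phantom():
    return render(melanoma_spec(seed=12))


def single_layer_spec(mu: float, **overrides) -> PhantomSpec:
    """Homogeneous noiseless medium starting at the image top."""
    base = dict(
        width=60,
        depth=220,
        surface_row=10,
        layers=(Layer(205, mu, 1.0),),
        speckle_sigma=0.0,
        entrance_rows=0,
        seed=0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def grid_search_mu(
    profile: np.ndarray,
    axial_pitch: float,
    mu_max: float = 10.0,
    step: float = 0.001,
) -> float:
    """Brute-force decay-rate estimate: linear-domain SSE over a mu grid.

    For each candidate mu the amplitude is the least-squares scale of
    exp(-2*mu*x) against the profile; the oracle returns the grid mu with
    the smallest residual.  Entirely independent of the log-linear fit it
    checks.
    """
    x = np.arange(profile.size) * (axial_pitch / 1000.0)
    grid = np.arange(0.0, mu_max + step / 2, step)
    basis = np.exp(-2.0 * grid[:, None] * x[None, :])  # n_grid x n_samples
    denom = (basis * basis).sum(axis=1)
    amp = (basis * profile[None, :]).sum(axis=1) / denom
    sse = ((profile[None, :] - amp[:, None] * basis) ** 2).sum(axis=1)
    return float(grid[np.argmin(sse)])
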