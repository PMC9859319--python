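import numpy as np
import pytest

from ecohealth.panel import PanelConfig, generate_dea_frontier_panel, generate_panel


@pytest.fixture(scope="session")
def small_panel():
    """6 regions x 8 years with noise, all predictors active."""
    return generate_panel(PanelConfig(n_regions=6, n_years=8, noise_sd=0.05, seed=123))


@pytest.fixture(scope="session")
def noiseless_ree_panel():
    """Outcomes depend on eco-efficiency alone, no noise: recovery fixture."""
    return generate_panel(
        PanelConfig(n_regions=6, n_years=10, noise_sd=0.0, control_strength=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def frontier_panel():
    """DEA fixture with known frontier membership (4 efficient of 7, 3 years)."""
    return generate_dea_frontier_panel(
        PanelConfig(n_regions=7, n_years=4, seed=31), n_efficient=4
    )


def pairwise_dominated(idx, inputs, goods, bads):
    """Brute-force dominance oracle: does any other unit weakly dominate `idx`
    (no worse in every input/good/bad, strictly better somewhere)?"""
    n = inputs.shape[0]
    for j in range(n):
        if j == idx:
            continue
        no_worse = (
            np.all(inputs[j] <= inputs[idx] + 1e-12)
            and np.all(goods[j] >= goods[idx] - 1e-12)
            and np.all(bads[j] <= bads[idx] + 1e-12)
        )
        strictly = (
            np.any(inputs[j] < inputs[idx] - 1e-9)
            or np.any(goods[j] > goods[idx] + 1e-9)
            or np.any(bads[j] < bads[idx] - 1e-9)
        )
        if no_worse and strictly:
            return True
    return False
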