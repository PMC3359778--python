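import numpy as np
import pandas as pd
import pytest

import shimmerwave as sw


@pytest.fixture(scope="session")
def lattice600():
    """Default-density lattice spanning the analysed nest area."""
    return sw.build_lattice((600.0, 600.0), 29.0, jitter_sd=2.0, seed=1)


@pytest.fixture(scope="session")
def lattice_small():
    """Small lattice for fast end-to-end runs."""
    return sw.build_lattice((150.0, 150.0), 29.0, jitter_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def directed_sim(lattice600):
    """One directed left-to-right wave with default parameters."""
    params = sw.WaveParams(dir_true=3, p_directed=1.0, seed=2)
    strengths, truth = sw.simulate_wave(lattice600, params)
    return strengths, truth


@pytest.fixture(scope="session")
def fitted(lattice600, directed_sim):
    strengths, truth = directed_sim
    return sw.ShimmeringModel.from_simulation(
        lattice600, strengths, truth=truth
    ).fit()


@pytest.fixture(scope="session")
def clean_sim(lattice600):
    """Noise-free directed wave (no trace noise, no amplitude spread)."""
    params = sw.WaveParams(
        dir_true=3, p_directed=1.0, noise_sd=0.0, amp_sd=0.0, seed=3
    )
    strengths, truth = sw.simulate_wave(lattice600, params)
    return strengths, truth


@pytest.fixture(scope="session")
def clean_fitted(lattice600, clean_sim):
    strengths, truth = clean_sim
    return sw.ShimmeringModel.from_simulation(
        lattice600, strengths, truth=truth
    ).fit()


def line_agents(n=5, spacing_mm=30.0):
    """Agents on a horizontal line, 30 mm apart (near neighbours only)."""
    table = pd.DataFrame(
        {
            "agent_id": np.arange(n),
            "x_mm": 20.0 + spacing_mm * np.arange(n),
            "y_mm": np.full(n, 20.0),
            "z_mm": np.zeros(n),
        }
    )
    table["x_px"] = (table["x_mm"] / 0.30).round().astype(int)
    table["y_px"] = (table["y_mm"] / 0.30).round().astype(int)
    return sw.AgentSet(table)


@pytest.fixture
def agents_line():
    return line_agents()
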