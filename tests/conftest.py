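import numpy as np
import pytest

import dynfc as d


@pytest.fixture(scope="session")
def small_connectome():
    """Dense 20-node modular connectome with a positive weight floor."""
    return d.generate_structural_connectome(
        d.SyntheticConnectomeSpec(20, 2, 1.0, 0.5, 0.05, seed=11))


@pytest.fixture(scope="session")
def medium_connectome():
    """50-node, 5-module connectome used for cohort-level checks."""
    return d.generate_structural_connectome(
        d.SyntheticConnectomeSpec(50, 5, 1.0, 0.3, 0.1, seed=7))


@pytest.fixture(scope="session")
def narrowband_series(small_connectome):
    """A seeded narrowband multi-region signal inside the analysis band."""
    rng = np.random.default_rng(5)
    n = small_connectome.n_rois
    t = np.arange(240) * 2.0
    phases0 = rng.uniform(0, 2 * np.pi, (n, 1))
    values = np.sin(2 * np.pi * 0.05 * t[None, :] + phases0)
    values += 0.05 * rng.standard_normal((n, 240))
    return d.RoiTimeSeries(values, 2.0, small_connectome.roi_labels,
                           subject_id="sub0", group="HC")


@pytest.fixture(scope="session")
def phase_series(narrowband_series):
    filtered = d.bandpass_filter(narrowband_series, 0.01, 0.09)
    return d.instantaneous_phase(filtered, edge_trim=10)


@pytest.fixture(scope="session")
def small_tensor(phase_series):
    return d.phase_connectivity_tensor(phase_series)
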