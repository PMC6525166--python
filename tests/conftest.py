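import numpy as np
import pytest

import ramanmcr as rm


@pytest.fixture(scope="session")
def axis():
    return rm.WavenumberAxis()


@pytest.fixture(scope="session")
def tp4_config():
    return rm.tp4()


@pytest.fixture(scope="session")
def nf4_config():
    return rm.nf4()


@pytest.fixture(scope="session")
def tp4_noiseless(tp4_config):
    """Default theophylline-like scenario with detector noise disabled."""
    return rm.realize_scenario(tp4_config, noiseless=True)


@pytest.fixture(scope="session")
def tp4_seed42(tp4_config):
    """Default theophylline-like scenario at the default noise, seed 42."""
    return rm.realize_scenario(tp4_config, seed=42)


@pytest.fixture(scope="session")
def small_config():
    """A reduced two-known / one-unknown scenario for fast I/O and CLI tests."""
    return rm.ScenarioConfig(
        name="small",
        axis=rm.config.AxisConfig(start=400, stop=1800, step=4),
        components=[
            rm.config.ComponentConfig(
                label="A", stable=True,
                bands=[rm.config.BandConfig(center=600, fwhm=20, amplitude=1.0),
                       rm.config.BandConfig(center=1200, fwhm=18, amplitude=0.4)],
            ),
            rm.config.ComponentConfig(
                label="B",
                bands=[rm.config.BandConfig(center=620, fwhm=20, amplitude=1.0),
                       rm.config.BandConfig(center=900, fwhm=18, amplitude=0.6)],
            ),
            rm.config.ComponentConfig(
                label="C", stable=True,
                bands=[rm.config.BandConfig(center=640, fwhm=20, amplitude=1.0),
                       rm.config.BandConfig(center=1500, fwhm=18, amplitude=0.7)],
            ),
        ],
        rates_per_min=[0.1, 0.04],
        t_max_min=60.0,
        t_step_min=3.0,
        n_positions=24,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return rm.realize_scenario(small_config)


def best_match_stats(result, truth_library, truth_C):
    """Cosine per resolved component and concentration RMSE after optimal
    component-to-truth assignment (Hungarian on the cosine matrix)."""
    from scipy.optimize import linear_sum_assignment

    def unit_rows(M):
        return M / np.linalg.norm(M, axis=1, keepdims=True)

    cos = unit_rows(result.S) @ unit_rows(truth_library.spectra).T
    _, perm = linear_sum_assignment(-cos)
    inv = np.argsort(perm)
    cosines = np.array([cos[i, perm[i]] for i in range(cos.shape[0])])
    rmse = float(np.sqrt(((result.C[:, inv] - truth_C) ** 2).mean()))
    return cosines, rmse
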