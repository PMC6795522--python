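import numpy as np
import pytest

from periscope import synthetic


@pytest.fixture(scope="session")
def small_params():
    """A compact nucleus keeping per-test generation cheap."""
    return synthetic.NucleusParams(
        semi_axes=(1.8, 1.5, 1.2), n_lad_spots=20, n_nonlad_spots=20,
        f_lad_peripheral=0.8, f_nonlad_peripheral=0.1, snr=10.0, seed=42,
    )


@pytest.fixture(scope="session")
def noiseless_cell():
    params = synthetic.NucleusParams(
        semi_axes=(1.8, 1.5, 1.2), n_lad_spots=15, n_nonlad_spots=15,
        f_lad_peripheral=0.8, f_nonlad_peripheral=0.1, snr=None, seed=7,
    )
    channels, truth = synthetic.generate_nucleus_image(params)
    return params, channels, truth


@pytest.fixture(scope="session")
def noisy_cell(small_params):
    channels, truth = synthetic.generate_nucleus_image(small_params)
    return small_params, channels, truth


@pytest.fixture(scope="session")
def csr_table():
    params = synthetic.StormParams(n_background=3000, localization_jitter_sigma=0.0, seed=19)
    return params, synthetic.generate_storm_localizations(params)


@pytest.fixture(scope="session")
def clustered_table():
    params = synthetic.StormParams(
        n_background=800, seed=23, localization_jitter_sigma=5.0,
        clusters=[(2500, 2500, 150, 250), (7000, 6000, 150, 250), (4500, 8200, 150, 250)],
    )
    return params, synthetic.generate_storm_localizations(params)
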