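import numpy as np
import pytest

import dstrfadapt as da


@pytest.fixture(scope="session")
def built_stimulus():
    """Small switching-noise stimulus: 3 blocks x 24 s, 12 s lead-in."""
    return da.build_session(n_blocks=3, block_duration=24.0, seed=7,
                            lead_in=12.0)


@pytest.fixture(scope="session")
def linear_session():
    """Noiseless static-linear session (4 electrodes, 6 x 30 s blocks)."""
    return da.make_session(n_blocks=6, block_duration=30.0, seed=5,
                           n_electrodes=4, encoder_kind="static_linear",
                           output_noise_sd=0.0, lead_in=12.0)


@pytest.fixture(scope="session")
def linear_session_filters():
    """The generating base filters of ``linear_session`` (same seeding)."""
    rng = np.random.default_rng(5 + 1)
    return [da.make_base_filter(int(rng.integers(2 ** 31)))
            for _ in range(4)]


@pytest.fixture(scope="session")
def tiny_cnn():
    """A randomly initialized small CNN results object for dSTRF math."""
    from dstrfadapt import _nn
    from dstrfadapt.cnn import CnnConfig, CnnHyper, CnnResults

    cfg = CnnConfig(n_layers=3, n_kernels=8, kernel_size=5,
                    dilations=(1, 2, 4), n_freq=6)
    rng = np.random.default_rng(0)
    params = _nn.init_params(cfg.n_freq, cfg.n_kernels, cfg.kernel_size,
                             cfg.n_layers, cfg.dilations, 3, rng)
    params.head_bias[:] = rng.standard_normal(3)
    return CnnResults(params, cfg, CnnHyper(), np.ones(cfg.n_freq),
                      np.zeros(1), np.zeros(0), 0, 3)
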