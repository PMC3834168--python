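"""Shared fixtures: phantoms are generated once per session and reused."""

import numpy as np
import pytest

import tractbench as tb
from tractbench import tensor


def fit_pipeline(dwi, mask=None):
    field = tensor.fit_tensor(dwi, mask)
    eigs = tensor.eigendecompose(field)
    return eigs, tensor.scalar_maps(eigs)


@pytest.fixture(scope="session")
def std_noiseless():
    """Standard phantom without noise, with fitted eigensystem and maps."""
    spec, gt = tb.make_standard_phantom(snr=None)
    dwi = tb.simulate_dwi(spec, gt)
    eigs, maps = fit_pipeline(dwi)
    return spec, gt, dwi, eigs, maps


@pytest.fixture(scope="session")
def std20():
    """Standard phantom at SNR 20 (the study's noise condition)."""
    spec, gt = tb.make_standard_phantom(snr=20.0, rng_seed=0)
    dwi = tb.simulate_dwi(spec, gt)
    eigs, maps = fit_pipeline(dwi)
    return spec, gt, dwi, eigs, maps


@pytest.fixture(scope="session")
def single_bundle20():
    spec, gt = tb.make_single_bundle_phantom(snr=20.0, rng_seed=0)
    dwi = tb.simulate_dwi(spec, gt)
    eigs, maps = fit_pipeline(dwi)
    return spec, gt, dwi, eigs, maps


@pytest.fixture(scope="session")
def table2():
    return tb.load_reference_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
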