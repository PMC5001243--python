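"""Shared fixtures: small synthetic datasets with known ground truth."""

import numpy as np
import pytest

import mspurify as mp


@pytest.fixture(scope="session")
def small_intensity():
    """Small model-generated intensity dataset (D=8, L=20, M=2, N=1e6)."""
    cfg = mp.SynthConfig(D=8, L=20, M=2, N=1e6, n_diff=6, effect=20.0,
                         beta_concentration=200.0, ref_alpha=1.0, seed=2)
    cases, controls, truth = mp.generate_intensity_mixtures(cfg)
    return cfg, cases, controls, truth


@pytest.fixture(scope="session")
def small_scan():
    """Small scan-level dataset (D=4, M=2, 12 features, 60 scans)."""
    cfg = mp.SynthConfig(D=4, L=20, M=2, N=1e6, n_diff=6, effect=8.0,
                         seed=11, scan_features=12)
    cases, controls, truth = mp.generate_scan_mixtures(cfg, n_features=12)
    return cfg, cases, controls, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def emg_shape():
    return mp.PeakShapeParams(mu=30.0, zeta=0.3, sigma=3.0)
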