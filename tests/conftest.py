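"""Shared fixtures: session-scoped simulated phantoms (all synthetic, no
binary fixture files)."""

from __future__ import annotations

from dataclasses import replace

import pytest

from phantomqc import desk_config, simulate_phantom_image
from phantomqc.phantom_sim import device_config_for


def mtf_config(sigma_mm: float, seed: int = 0, **overrides):
    """Noiseless configuration with an enlarged Cu square so a wide ESF band
    (150 px) fits inside it; used for MTF-oracle comparisons."""
    cfg = desk_config(seed=seed, blur_sigma_mm=sigma_mm, poisson_gain=0.0,
                      electronic_noise_sd=0.0)
    spec = replace(cfg.spec, cu_square_side_mm=40.0, cu_center_frac=(0.35, 0.35),
                   al_center_frac=(0.78, 0.22))
    return replace(cfg, spec=spec, **overrides)


MTF_BAND_PX = 150


@pytest.fixture(scope="session")
def desk_cfg():
    return desk_config(seed=1)


@pytest.fixture(scope="session")
def desk_sim(desk_cfg):
    """(image, truth) for the standard noisy desk phantom."""
    return simulate_phantom_image(desk_cfg)


@pytest.fixture(scope="session")
def desk_device_cfg(desk_cfg):
    return device_config_for(desk_cfg)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return desk_config(seed=0, poisson_gain=0.0, electronic_noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_sim(noiseless_cfg):
    return simulate_phantom_image(noiseless_cfg)
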