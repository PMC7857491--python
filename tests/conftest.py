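import numpy as np
import pytest

from efqokit import standard_config
from efqokit.simulate import simulate_plate


@pytest.fixture
def clean_config():
    """Noise-free, fully-quenched standard assay in the linear regime.

    Vmax is low enough that the default 12-read window consumes < 2% of
    the substrate, so the window chord is an unbiased initial rate.
    """
    return standard_config(noise_sd=0.0, quench_efficiency=1.0, Vmax=5e-10)


@pytest.fixture
def standard_plate(clean_config):
    """Two controls plus triplicate sample wells, noise-free."""
    design = [
        ("A01", "substrate_control", {}),
        ("A02", "enzyme_control", {}),
        ("B01", "sample", {"condition": "std", "replicate": 1}),
        ("B02", "sample", {"condition": "std", "replicate": 2}),
        ("B03", "sample", {"condition": "std", "replicate": 3}),
    ]
    return simulate_plate(design, clean_config, seed=11)


def true_initial_rate_au(cfg, vmax_factor=1.0):
    """Analytic initial fluorescence rate k_AU·V·Vmax_eff·S0/(Km+S0)."""
    vmax = cfg.Vmax * vmax_factor
    return cfg.k_AU * cfg.volume * vmax * cfg.S0 / (cfg.Km + cfg.S0)
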