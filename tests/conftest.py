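import numpy as np
import pytest

import allelecall as ac
from allelecall.simulate import KitTemplate, PanelDesign


@pytest.fixture
def settings():
    return ac.AnalysisSettings(control_marker="B2m")


@pytest.fixture
def small_design():
    """Two kits, four samples, one plate; keeps unit tests fast."""
    kits = (
        KitTemplate(name="kit1", snps=(("HA01", ("A", "G")), ("HA02", ("C", "T")))),
        KitTemplate(name="kit2", snps=(("HA03", ("C", "G")),), indels=("UGT2b17",)),
    )
    return PanelDesign(kits=kits, n_samples=4, samples_per_plate=4)


@pytest.fixture
def quiet_noise():
    return ac.NoiseProfile(noise_sd=0.0, drift_slope=0.0)


@pytest.fixture
def small_study(small_design, quiet_noise):
    return ac.simulate_experiment(small_design, truth_seed=11, noise=quiet_noise)


def clean_b4(e=20.0, k=0.8, d=1000.0, n_cycles=40):
    x = np.arange(1, n_cycles + 1, dtype=float)
    from allelecall.curves import model_predict

    return x, model_predict("b4", x, -k, 0.0, d, e, 1.0)
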