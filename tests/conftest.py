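from pathlib import Path

import numpy as np
import pytest

import zebratk as z

#: Users who have converted the published supplementary tables to CSV can
#: drop them here (canonical columns chemical, log10_kow, log10_bcf, ...);
#: data-dependent checks run against them and are skipped otherwise.
SUPPLEMENTARY_DIR = Path(__file__).resolve().parent.parent / "data" / "supplementary"


def supplementary_table(name: str):
    path = SUPPLEMENTARY_DIR / name
    if not path.exists():
        pytest.skip(
            f"supplementary table {name} not available under {SUPPLEMENTARY_DIR}; "
            "place a CSV conversion there to run this data-dependent check"
        )
    return z.read_dataset(path)


@pytest.fixture(scope="session")
def phys7c():
    return z.default_physiology_7c()


@pytest.fixture(scope="session")
def phys1c():
    return z.default_physiology_1c()


@pytest.fixture(scope="session")
def chem3():
    return z.Chemical("probe", 3.0)


@pytest.fixture(scope="session")
def noisefree_dataset():
    """40 chemicals generated from the 7C model at the default truth pair."""
    return z.generate_synthetic(z.SyntheticSpec(n_chemicals=40, seed=2024))


@pytest.fixture(scope="session")
def analog_dataset():
    """Adult-data analogue: regression truth + sd-0.8 log10 BCF noise."""
    return z.generate_synthetic(
        z.SyntheticSpec(
            n_chemicals=76, generator="from_regression", noise_sd=0.8, seed=76
        )
    )


@pytest.fixture
def small_pso():
    return z.PSOConfig(
        bounds=((1.0, 2.0),), n_particles=150, max_iterations=200,
        score_cutoff=0.999,
    )
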