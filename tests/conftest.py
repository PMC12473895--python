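import numpy as np
import pandas as pd
import pytest

from phenopred.design import DesignSpec
from phenopred.simulate import (
    FactorialSimulator,
    SpectraGenSpec,
    TraitGenArchitecture,
)


@pytest.fixture(scope="session")
def small_design():
    """4 x 4 factorial, 2 environments x 2 replicates."""
    return DesignSpec(4, 4, {"E1": 2, "E2": 2})


@pytest.fixture(scope="session")
def full_design():
    """The canonical 10 x 10 factorial in 8 environments with 2 replicates."""
    return DesignSpec(10, 10, {f"E{i + 1}": 2 for i in range(8)})


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """A coherent small synthetic dataset (genotypes, records, spectra)."""
    sim = FactorialSimulator(
        design=small_design,
        n_markers=400,
        spectra_spec=SpectraGenSpec(stop_nm=480.0),  # 160 bands
    )
    return sim.simulate(seed=42)


@pytest.fixture(scope="session")
def medium_dataset():
    """10 x 10 factorial, 4 environments: enough structure for CV runs."""
    sim = FactorialSimulator(
        design=DesignSpec(10, 10, {f"E{i + 1}": 2 for i in range(4)}),
        n_markers=800,
        spectra_spec=SpectraGenSpec(stop_nm=500.0),  # 200 bands
    )
    return sim.simulate(seed=7)


def iid_records(design, components, mu=5.0, seed=0, trait="trait"):
    """Simulate records with purely i.i.d. effects (kernel-free mode)."""
    arch = TraitGenArchitecture(components=components, mu=mu, genomic=False)
    from phenopred.simulate import simulate_trait_records

    return simulate_trait_records(design, arch, seed=seed, trait=trait)
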