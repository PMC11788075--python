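import numpy as np
import pandas as pd
import pytest

from dielmat.synthetic import (
    ModulePlan,
    NoiseModel,
    SampleDesign,
    generate_catalog,
    generate_diel_counts,
)


@pytest.fixture(scope="session")
def small_catalog():
    return generate_catalog(
        ["taxA", "taxB", "taxC"], genes_per_taxon=8, n_mags_per_taxon=3, seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_planted_series(
    n_series=3,
    n_times=10,
    module_genes=50,
    n_modules=5,
    flat_genes=250,
    amplitude=4.0,
    dispersion=0.1,
    seed=0,
    spacing=None,
    sunrise=6.0,
    sunset=19.0,
):
    """Planted multi-series count scenario at the ortholog level.

    Phases are placed on the sampling grid with maximal mutual separation.
    Returns (countsets, truth, designs, catalog).
    """
    if spacing is None:
        times = np.linspace(0, 24, n_times, endpoint=False)
    else:
        times = np.arange(0, 24, spacing)
    step = len(times) // n_modules
    phases = [float(times[(i * step) % len(times)]) for i in range(n_modules)]
    genes_per_taxon = module_genes * n_modules + flat_genes
    catalog = generate_catalog(
        ["taxZ"], genes_per_taxon=genes_per_taxon, n_mags_per_taxon=1, seed=seed
    )
    plans = [
        ModulePlan(f"P{i + 1}", phase_hours=phases[i], amplitude=amplitude,
                   member_taxa={"taxZ": module_genes})
        for i in range(n_modules)
    ]
    designs = [
        SampleDesign(f"S{k + 1}", times, sunrise=sunrise, sunset=sunset)
        for k in range(n_series)
    ]
    noise = NoiseModel(dispersion=dispersion)
    countsets, _, truth = generate_diel_counts(
        catalog, designs, plans, noise, seed=seed + 1
    )
    return countsets, truth, designs, catalog


@pytest.fixture(scope="session")
def planted_series():
    return make_planted_series(seed=5)
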