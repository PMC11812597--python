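"""Shared fixtures.

Heavy equilibrium computations are session-scoped: the diffusion-rescaled
selection grid (N = 2,000 diploids with 2N*mu and 2N*s_het preserved
relative to the production population of 20,000) backs the simulator and
pipeline tests, and the mutation-selection-balance distribution backs the
strong-selection limit checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from traitspec import popgen, synthetic

#: diffusion rescaling factor between the production population (20,000
#: diploids) and the desk-scale population used in tests (2,000 diploids)
SCALE = 10.0


@pytest.fixture(scope="session")
def scaled_params() -> popgen.PopulationParams:
    return popgen.PopulationParams(2000, 1.25e-7)


@pytest.fixture(scope="session")
def scaled_grid(scaled_params) -> popgen.SelectionGrid:
    """Production 50-point grid, diffusion-rescaled to N=2,000."""
    return popgen.build_selection_grid(scaled_params, n_points=50, lo=1e-6, hi=0.5)


@pytest.fixture(scope="session")
def balance_dist() -> popgen.FrequencyDistribution:
    """Strong-selection equilibrium at N=2,000, mu=1e-6, s_het=0.01."""
    return popgen.stationary_distribution(popgen.PopulationParams(2000, 1e-6), 0.01)


@pytest.fixture(scope="session")
def tiny_grid() -> popgen.SelectionGrid:
    """A small, fast grid for lookup and sampling mechanics."""
    params = popgen.PopulationParams(200, 1e-5)
    return popgen.build_selection_grid(params, n_points=8, lo=1e-4, hi=0.5)


@pytest.fixture(scope="session")
def synth_config() -> synthetic.SyntheticConfig:
    return synthetic.SyntheticConfig(seed=1, shet_lookup_scale=SCALE)


@pytest.fixture(scope="session")
def synth_universe(synth_config, scaled_grid):
    """Full default synthetic universe: genes, truth, burden, GWAS."""
    genes, truth = synthetic.generate_genes(synth_config, 1)
    burden = synthetic.generate_burden_stats(truth, synth_config.burden_n_samples, 11)
    gwas = synthetic.generate_gwas_stats(truth, synth_config, scaled_grid, 12)
    return {"config": synth_config, "genes": genes, "truth": truth,
            "burden": burden, "gwas": gwas}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
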