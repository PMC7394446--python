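import numpy as np
import pandas as pd
import pytest

from mprabayes.io import compute_depth_factors
from mprabayes.nb import VariantData
from mprabayes.priors import GammaPrior, PriorSet, collect_mles
from mprabayes.simulate import SimConfig, simulate_assay


@pytest.fixture(scope="session")
def small_assay():
    """60-variant assay with 20% functional variants, plus depth factors."""
    table, truth = simulate_assay(
        SimConfig(n_variants=60, frac_functional=0.2, seed=11)
    )
    depths = compute_depth_factors(table)
    return table, truth, depths


@pytest.fixture(scope="session")
def small_mles(small_assay):
    table, _, depths = small_assay
    return collect_mles(table, depths, seed=11)


@pytest.fixture(scope="session")
def generic_priors():
    """A plausible PriorSet matching the simulator's truth hyperpriors."""
    return PriorSet(
        mu_dna=GammaPrior(5.0, 0.1),
        mu_rna_ref=GammaPrior(4.0, 4.0),
        mu_rna_alt=GammaPrior(4.0, 4.0),
        phi_dna=GammaPrior(10.0, 1.0),
        phi_rna=GammaPrior(10.0, 1.0),
    )


def make_variant_data(
    rng,
    n_per_allele=10,
    n_dna=3,
    n_rna=5,
    mu_dna_mean=50.0,
    mu_ref=1.0,
    mu_alt=1.0,
    phi=10.0,
    depths_dna=None,
    depths_rna=None,
    variant_id="v0",
):
    """Draw one variant's counts from the NB model at known parameters."""
    b = 2 * n_per_allele
    alt = np.arange(b) >= n_per_allele
    mu_dna = rng.gamma(5.0, mu_dna_mean / 5.0, size=b)
    mu_al = np.where(alt, mu_alt, mu_ref)
    d_dna = np.ones(n_dna) if depths_dna is None else np.asarray(depths_dna, float)
    d_rna = np.ones(n_rna) if depths_rna is None else np.asarray(depths_rna, float)
    m_dna = mu_dna[:, None] * d_dna
    m_rna = (mu_dna * mu_al)[:, None] * d_rna
    dna = rng.negative_binomial(phi, phi / (phi + m_dna)).astype(float)
    rna = rng.negative_binomial(phi, phi / (phi + m_rna)).astype(float)
    return VariantData(variant_id, dna, rna, alt, d_dna, d_rna)
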