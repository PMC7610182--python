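import numpy as np
import pytest

from smokemr import SimulationConfig, simulate_summary_stats


def arrays_from_records(exposure, outcome):
    """Extract (gamma_hat, sigma_gamma, Gamma_hat, sigma_Gamma) assuming the
    generator's aligned allele labels (no harmonisation exercise)."""
    g = np.array([r.beta for r in exposure])
    sg = np.array([r.se for r in exposure])
    G = np.array([r.beta for r in outcome])
    sG = np.array([r.se for r in outcome])
    return g, sg, G, sG


def clean_sim(seed, **kwargs):
    """Summary-statistic draw with allele bookkeeping switched off, so the
    exposure/outcome records are already aligned."""
    defaults = dict(
        n_snp=100,
        theta=np.log(2),
        pleiotropy="none",
        gamma_sd=0.2,
        n_exposure=1_232_091,
        n_outcome=1_232_091,
        palindromic_frac=0.0,
        strand_flip_frac=0.0,
        allele_swap_frac=0.0,
    )
    defaults.update(kwargs)
    cfg = SimulationConfig(seed=seed, **defaults)
    exp, out, truth = simulate_summary_stats(cfg)
    return arrays_from_records(exp, out), truth


@pytest.fixture
def small_dataset():
    """A 20-SNP no-pleiotropy dataset with theta = ln 2."""
    (g, sg, G, sG), truth = clean_sim(seed=11, n_snp=20)
    return g, sg, G, sG
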