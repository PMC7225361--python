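import numpy as np
import pytest

from grsgxe import (CohortTable, GenotypePanel, GenotypeSimConfig,
                    VariantRecord, assign_causal_snps, get_scenario,
                    sample_effects, sample_exposure, simulate_ld_genotypes,
                    simulate_trait)


def make_panel(dosages, positions=None, chromosome="1", mafs=None,
               call_rates=None, hwe_ps=None):
    """Build a GenotypePanel from a raw dosage array with default metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, L = dosages.shape
    variants = []
    for j in range(L):
        col = dosages[:, j]
        obs = col[~np.isnan(col)]
        freq = obs.mean() / 2.0 if obs.size else 0.0
        variants.append(VariantRecord(
            id=f"v{j}", chromosome=chromosome,
            position=positions[j] if positions is not None else 1 + j,
            allele_minor="A", allele_major="B",
            maf=mafs[j] if mafs is not None else min(freq, 1 - freq),
            call_rate=call_rates[j] if call_rates is not None
            else obs.size / n,
            hwe_p=hwe_ps[j] if hwe_ps is not None else 1.0))
    return GenotypePanel(dosages=dosages, variants=variants,
                         sample_ids=[f"S{i}" for i in range(n)])


@pytest.fixture
def small_panel():
    """5 subjects x 3 SNPs with hand-countable dosages and one missing call."""
    d = np.array([[0, 1, 2],
                  [1, 0, 0],
                  [2, 1, 1],
                  [0, 0, np.nan],
                  [1, 2, 0]], dtype=float)
    return make_panel(d)


@pytest.fixture(scope="session")
def sim_panel():
    """A moderately sized LD panel shared across tests (read-only)."""
    return simulate_ld_genotypes(GenotypeSimConfig(
        n_subjects=1500, gene_size=48, seed=11))


@pytest.fixture(scope="session")
def sim_cohort(sim_panel):
    """A gaussian scenario-1 cohort on `sim_panel` (read-only)."""
    causal = assign_causal_snps(sim_panel, 4, seed=12)
    sc = get_scenario(1)
    eff = sample_effects(sc, "gaussian", seed=13)
    e = sample_exposure("binary", sim_panel.n_samples, 0.2, seed=14)
    sim = simulate_trait(sim_panel, causal, eff, e, seed=15, scenario=sc)
    return sim


def make_single_snp_cohort(seed, n=800, family="gaussian", beta_int=0.25):
    """One-SNP dataset with a real interaction, for L = 1 reduction checks."""
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.3, n).astype(float)
    e = rng.binomial(1, 0.5, n).astype(float)
    lp = 0.3 * g + 0.3 * e + beta_int * g * e
    if family == "gaussian":
        y = lp + rng.standard_normal(n)
    else:
        from scipy.special import expit
        y = rng.binomial(1, expit(-1.0 + lp)).astype(float)
    panel = make_panel(g[:, None])
    cohort = CohortTable(y=y, exposure=e, covariates=np.zeros((n, 0)),
                         family=family)
    return cohort, panel
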