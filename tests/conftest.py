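"""Shared fixtures and independent oracles for the test suite."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from resistkit import BioassayTable, GeneticArchitecture, Genotype


def probit_grid_loglik(table, n_grid=161, n_zoom=5):
    """Independent brute-force oracle: maximum binomial log-likelihood of
    the probit line by dense grid search over (log10 LC50, slope), zoomed
    iteratively. Includes the binomial coefficient constants so the value
    is comparable with a GLM log-likelihood. Never calls the fitter.
    """
    pooled = (table.df[table.df["concentration_ug_ml"] > 0]
              .groupby("concentration_ug_ml")[["n_total", "n_dead"]]
              .sum().reset_index())
    x = np.log10(pooled["concentration_ug_ml"].to_numpy())
    n = pooled["n_total"].to_numpy(float)
    dead = pooled["n_dead"].to_numpy(float)
    const = float(np.sum(gammaln(n + 1) - gammaln(dead + 1)
                         - gammaln(n - dead + 1)))
    m_lo, m_hi = x.min() - 1.5, x.max() + 1.5
    b_lo, b_hi = 0.05, 12.0
    best = -np.inf
    for _ in range(n_zoom):
        ms = np.linspace(m_lo, m_hi, n_grid)
        bs = np.linspace(b_lo, b_hi, n_grid)
        M, B = np.meshgrid(ms, bs, indexing="ij")
        # p[i,j,k] = Phi(B * (x_k - M))
        z = B[..., None] * (x[None, None, :] - M[..., None])
        p = np.clip(stats.norm.cdf(z), 1e-300, 1 - 1e-16)
        ll = (dead * np.log(p) + (n - dead) * np.log1p(-p)).sum(axis=-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = max(best, ll[i, j])
        dm, db = (m_hi - m_lo) / (n_grid - 1), (b_hi - b_lo) / (n_grid - 1)
        m_lo, m_hi = ms[i] - 2 * dm, ms[i] + 2 * dm
        b_lo, b_hi = max(bs[j] - 2 * db, 1e-3), bs[j] + 2 * db
    return best + const


def table_from_counts(concs, n, dead, strain="S", compound="bifenthrin"):
    """Build a single-line BioassayTable from parallel count arrays."""
    n = np.broadcast_to(np.asarray(n), np.shape(concs))
    return BioassayTable(pd.DataFrame({
        "strain": strain, "compound": compound,
        "concentration_ug_ml": np.asarray(concs, float),
        "n_total": np.asarray(n, int), "n_dead": np.asarray(dead, int)}))


def simulate_single_line(lc50, slope, concs, n_per_conc, seed,
                         strain="S"):
    """Binomial draws straight from the probit curve (no genetics layer):
    an independent data generator for fitter tests."""
    rng = np.random.default_rng(seed)
    concs = np.asarray(concs, float)
    p = stats.norm.cdf(slope * (np.log10(concs) - np.log10(lc50)))
    dead = rng.binomial(n_per_conc, p)
    return table_from_counts(concs, n_per_conc, dead, strain=strain)


@pytest.fixture
def sus_like_arch():
    """One-locus architecture matching the study strains: LC50s 0.64 and
    3,080.95 μg/mL, F1 placed at Stone's D = 0.13."""
    return GeneticArchitecture.from_lc50s(0.64, 3080.95, slope=1.5,
                                          n_loci=1, d_stone=0.13)


@pytest.fixture
def seeded_bioassay(sus_like_arch):
    from resistkit import simulate_bioassay
    g = Genotype.homozygous_s(1)
    return simulate_bioassay(sus_like_arch, {g: 1.0},
                             np.geomspace(0.18, 5.6, 7), 40, seed=123,
                             strain="Sus").table
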