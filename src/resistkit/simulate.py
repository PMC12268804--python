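"""Seeded simulators of bioassays, crossing experiments and cage populations.

These generate data with exactly the statistical structure the analysis
modules assume: binomial mortality at log-spaced concentrations under
genotype-specific probit tolerance curves, Mendelian F1/backcross
segregation under one- or k-locus architectures, and discrete-generation
random-mating cage populations founded at stated R:S proportions with an
optional viability fitness cost. All randomness flows from an explicit
seed; the same seed and configuration give byte-identical tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bioassay import BioassayTable
from .errors import ContractError
from .genetics import (GeneticArchitecture, Genotype, cross_distribution,
                       make_cross)
from .inheritance import monogenic_test

#: Backcross screening concentrations (μg a.i./mL) used by the inheritance
#: experiment and the power study: six log-spaced doses spanning the
#: heterozygote response range.
BACKCROSS_CONCENTRATIONS = (3.2, 10.0, 32.0, 100.0, 320.0, 560.0)


@dataclass
class SimulatedBioassay:
    """A bioassay table plus the provenance needed to regenerate it."""
    table: BioassayTable
    provenance: dict

    @property
    def df(self) -> pd.DataFrame:
        return self.table.df


def _as_mix(mix: Dict[Genotype, float]) -> Dict[Genotype, float]:
    tot = sum(mix.values())
    if abs(tot - 1.0) > 1e-9:
        raise ContractError(f"genotype frequencies sum to {tot}, not 1")
    return mix


def simulate_bioassay(arch: GeneticArchitecture,
                      genotype_mix: Dict[Genotype, float],
                      concentrations: Sequence[float], n_per_conc: int,
                      seed, strain: str = "sim",
                      compound: str = "bifenthrin") -> SimulatedBioassay:
    """Simulate one concentration-mortality assay.

    At each concentration every exposed insect draws its genotype from the
    mixture, then dies with probability ``Phi(beta * (log10 c - tolerance))``.
    Counts are aggregated to one row per concentration.
    """
    mix = _as_mix(genotype_mix)
    conc = np.asarray(concentrations, float)
    if (conc <= 0).any():
        raise ContractError("concentrations must be positive")
    if n_per_conc <= 0:
        raise ContractError("n_per_conc must be positive")
    rng = np.random.default_rng(seed)
    genos = list(mix)
    freqs = np.array([mix[g] for g in genos])
    rows = []
    for c in np.sort(conc):
        counts = rng.multinomial(n_per_conc, freqs)
        dead = 0
        for g, m in zip(genos, counts):
            if m:
                dead += rng.binomial(m, arch.mortality(g, c))
        rows.append({"strain": strain, "compound": compound,
                     "concentration_ug_ml": float(c),
                     "n_total": int(n_per_conc), "n_dead": int(dead)})
    table = BioassayTable(pd.DataFrame(rows))
    prov = {"architecture": {"n_loci": arch.n_loci, "x_ss": arch.x_ss,
                             "x_rr": arch.x_rr, "h": arch.h,
                             "slope": arch.slope},
            "genotype_mix": {str(g.counts): f for g, f in mix.items()},
            "seed": seed}
    return SimulatedBioassay(table=table, provenance=prov)


def simulate_inheritance_experiment(
        arch: GeneticArchitecture, seed, n_per_conc: int = 40,
        concentrations: Optional[Dict[str, Sequence[float]]] = None
) -> Dict[str, SimulatedBioassay]:
    """Simulate the full crossing design: parents, reciprocal F1s, and the
    four backcrosses of each F1 to the susceptible parent.

    Reciprocal-cross direction is metadata only (the architecture is
    autosomal), so H1/H2 and the four backcross tables differ only by their
    random draws. Default concentration grids bracket each strain's
    response; backcrosses use :data:`BACKCROSS_CONCENTRATIONS`.
    """
    k = arch.n_loci
    ss, rr = Genotype.homozygous_s(k), Genotype.homozygous_r(k)
    f1 = cross_distribution(rr, ss)          # all-heterozygous
    bc = cross_distribution(Genotype.heterozygous(k), ss)
    if concentrations is None:
        concentrations = {}
    conc = {
        "Sus": np.geomspace(0.18, 5.6, 7),
        "Bif-R": np.geomspace(320.0, 10_000.0, 6),
        "H1": np.geomspace(3.2, 3_200.0, 7),
        "H2": np.geomspace(3.2, 3_200.0, 7),
        "SusF_x_H1M": BACKCROSS_CONCENTRATIONS,
        "SusM_x_H1F": BACKCROSS_CONCENTRATIONS,
        "SusF_x_H2M": BACKCROSS_CONCENTRATIONS,
        "SusM_x_H2F": BACKCROSS_CONCENTRATIONS,
    }
    conc.update(concentrations)
    mixes = {"Sus": {ss: 1.0}, "Bif-R": {rr: 1.0}, "H1": f1, "H2": f1,
             "SusF_x_H1M": bc, "SusM_x_H1F": bc,
             "SusF_x_H2M": bc, "SusM_x_H2F": bc}
    children = np.random.SeedSequence(seed).spawn(len(mixes))
    out = {}
    for (name, mix), child in zip(mixes.items(), children):
        out[name] = simulate_bioassay(arch, mix, conc[name], n_per_conc,
                                      np.random.default_rng(child),
                                      strain=name)
        out[name].provenance["seed"] = {"root": seed, "strain": name}
    return out


# ---------------------------------------------------------------------------
# cage populations: stability of resistance without selection
# ---------------------------------------------------------------------------
@dataclass
class StabilityConfig:
    """Configuration of a cage-population stability experiment.

    ``founding_rr`` is the fraction of RR adults at founding (the rest are
    SS — e.g. 0.8 for the 80R:20S treatment). ``fitness_cost`` s in [0, 1)
    acts on viability before mating with relative fitnesses
    RR = 1 - s, RS = 1 - h_c * s, SS = 1 (``cost_dominance`` = h_c).
    ``diagnostic_dose`` is the single monitoring concentration;
    ``n_tested`` insects are screened there each generation. Deterministic
    mode propagates expected frequencies and ignores ``census`` and
    ``seed``.
    """
    founding_rr: float
    generations: int
    census: int = 600
    fitness_cost: float = 0.0
    cost_dominance: float = 0.5
    diagnostic_dose: float = 100.0
    n_tested: int = 480
    mode: str = "stochastic"
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.founding_rr <= 1.0:
            raise ContractError("founding_rr must be in [0, 1]")
        if self.generations < 1:
            raise ContractError("generations must be >= 1")
        if not 0.0 <= self.fitness_cost < 1.0:
            raise ContractError("fitness_cost s must be in [0, 1)")
        if not 0.0 <= self.cost_dominance <= 1.0:
            raise ContractError("cost_dominance must be in [0, 1]")
        if self.mode not in ("stochastic", "deterministic"):
            raise ContractError(f"unknown mode {self.mode!r}")
        if self.mode == "stochastic" and self.seed is None:
            raise ContractError("stochastic mode requires a seed")


def _select(freqs: np.ndarray, s: float, h_c: float) -> np.ndarray:
    """Viability selection on (RR, RS, SS) frequencies by the fitness cost."""
    w = np.array([1.0 - s, 1.0 - h_c * s, 1.0])
    f = freqs * w
    return f / f.sum()


def _expected_survival(arch: GeneticArchitecture, freqs: np.ndarray,
                       dose: float) -> float:
    genos = [Genotype.homozygous_r(1), Genotype.heterozygous(1),
             Genotype.homozygous_s(1)]
    return float(sum(f * (1.0 - arch.mortality(g, dose))
                     for g, f in zip(genos, freqs)))


def simulate_stability(cfg: StabilityConfig, arch: GeneticArchitecture
                       ) -> pd.DataFrame:
    """Multi-generation cage population without insecticide exposure.

    Requires a one-locus architecture. Each generation: (i) viability
    selection by the fitness cost, (ii) random mating — offspring at
    Hardy-Weinberg proportions of the post-selection R frequency,
    (iii) in stochastic mode, multinomial sampling of ``census``
    individuals. Generation 0 is the founding RR/SS mixture.

    Returns one row per generation with genotype frequencies, the R allele
    frequency, expected survival at the diagnostic dose, and (stochastic
    mode) simulated survivor counts among ``n_tested`` screened insects.
    """
    if arch.n_loci != 1:
        raise ContractError("stability simulation requires a 1-locus "
                            "architecture")
    rng = (np.random.default_rng(cfg.seed)
           if cfg.mode == "stochastic" else None)
    genos = [Genotype.homozygous_r(1), Genotype.heterozygous(1),
             Genotype.homozygous_s(1)]
    freqs = np.array([cfg.founding_rr, 0.0, 1.0 - cfg.founding_rr])
    rows = []

    def record(gen: int, f: np.ndarray) -> None:
        surv = _expected_survival(arch, f, cfg.diagnostic_dose)
        row = {"generation": gen, "freq_rr": f[0], "freq_rs": f[1],
               "freq_ss": f[2], "allele_freq_r": f[0] + f[1] / 2.0,
               "expected_survival": surv, "n_tested": cfg.n_tested}
        if rng is not None:
            counts = rng.multinomial(cfg.n_tested, f)
            alive = sum(rng.binomial(m, 1.0 - arch.mortality(g,
                                                             cfg.diagnostic_dose))
                        for g, m in zip(genos, counts) if m)
            row["n_survived"] = int(alive)
            row["observed_survival"] = alive / cfg.n_tested
        rows.append(row)

    record(0, freqs)
    for gen in range(1, cfg.generations + 1):
        post = _select(freqs, cfg.fitness_cost, cfg.cost_dominance)
        p = post[0] + post[1] / 2.0
        freqs = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
        if rng is not None:
            counts = rng.multinomial(cfg.census, freqs)
            freqs = counts / cfg.census
        record(gen, freqs)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# response to selection episodes
# ---------------------------------------------------------------------------
def population_lc50(arch: GeneticArchitecture,
                    mix: Dict[Genotype, float]) -> float:
    """Effective LC50 of a genotype mixture: the concentration where the
    mixture mortality curve crosses 50%, by root finding on the log10
    scale."""
    mix = _as_mix(mix)
    lo = arch.x_ss - 6.0 / arch.slope
    hi = arch.x_rr + 6.0 / arch.slope

    def f(x):
        return arch.mixture_mortality(mix, 10.0 ** x) - 0.5

    return float(10.0 ** optimize.brentq(f, lo, hi, xtol=1e-10))


def selection_response(arch: GeneticArchitecture, founding_r_freq: float,
                       generations: int,
                       dose_schedule: Union[float, Sequence[float], None],
                       fitness_cost: float = 0.0,
                       cost_dominance: float = 0.5,
                       mode: str = "deterministic",
                       census: int = 600,
                       seed: Optional[int] = None) -> pd.DataFrame:
    """One-locus allele-frequency dynamics under insecticide selection
    episodes and/or a fitness cost, tracking the population LC50 and its
    resistance ratio against the susceptible homozygote.

    ``dose_schedule`` is the exposure concentration applied to each
    generation before mating (a scalar, one value per generation, or None
    for no exposure). Survival of genotype g at dose d,
    ``1 - Phi(beta (log10 d - tolerance_g))``, multiplies the fitness-cost
    viability. Deterministic mode propagates expectations; stochastic mode
    resamples ``census`` individuals per generation.
    """
    if arch.n_loci != 1:
        raise ContractError("selection response requires a 1-locus "
                            "architecture")
    if not 0.0 <= founding_r_freq <= 1.0:
        raise ContractError("founding_r_freq must be in [0, 1]")
    if not 0.0 <= fitness_cost < 1.0:
        raise ContractError("fitness_cost s must be in [0, 1)")
    if mode == "stochastic" and seed is None:
        raise ContractError("stochastic mode requires a seed")
    if dose_schedule is None:
        doses = [None] * generations
    elif np.isscalar(dose_schedule):
        doses = [float(dose_schedule)] * generations
    else:
        doses = list(dose_schedule)
        if len(doses) != generations:
            raise ContractError("dose_schedule length must equal "
                                "generations")
    rng = np.random.default_rng(seed) if mode == "stochastic" else None
    genos = [Genotype.homozygous_r(1), Genotype.heterozygous(1),
             Genotype.homozygous_s(1)]
    lc50_ss = 10.0 ** arch.x_ss
    p = founding_r_freq
    freqs = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
    rows = []

    def record(gen, f, dose):
        mix = dict(zip(genos, f))
        mix = {g: fr for g, fr in mix.items() if fr > 0}
        lc = population_lc50(arch, mix)
        rows.append({"generation": gen, "dose": dose,
                     "allele_freq_r": f[0] + f[1] / 2.0,
                     "freq_rr": f[0], "freq_rs": f[1], "freq_ss": f[2],
                     "population_lc50": lc,
                     "resistance_ratio": lc / lc50_ss})

    record(0, freqs, None)
    for gen, dose in enumerate(doses, start=1):
        w = np.array([1.0 - fitness_cost,
                      1.0 - cost_dominance * fitness_cost, 1.0])
        if dose is not None:
            w = w * np.array([1.0 - float(arch.mortality(g, dose))
                              for g in genos])
        f = freqs * w
        tot = f.sum()
        if tot <= 0:
            raise ContractError(f"population extinct at generation {gen}")
        f = f / tot
        p = f[0] + f[1] / 2.0
        freqs = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
        if rng is not None:
            freqs = rng.multinomial(census, freqs) / census
        record(gen, freqs, dose)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# power of the monogenic test across architectures
# ---------------------------------------------------------------------------
def _backcross_rows_exact_expectation(arch: GeneticArchitecture,
                                      concentrations, n_per_conc, rng):
    """One simulated backcross screen with expectations computed from the
    generating model (parental mortalities treated as known)."""
    k = arch.n_loci
    ss = Genotype.homozygous_s(k)
    f1 = Genotype.heterozygous(k)
    bc = cross_distribution(f1, ss)
    genos = list(bc)
    freqs = np.array([bc[g] for g in genos])
    rows = []
    for c in concentrations:
        a = float(arch.mortality(f1, c))     # heterozygous parent strain
        b = float(arch.mortality(ss, c))     # susceptible parent strain
        counts = rng.multinomial(n_per_conc, freqs)
        dead = sum(int(rng.binomial(m, arch.mortality(g, c)))
                   for g, m in zip(genos, counts) if m)
        rows.append({"concentration": c, "n_dead": dead,
                     "n_total": n_per_conc, "expected_p": (a + b) / 2.0})
    return rows


def power_study(architectures: Dict[str, GeneticArchitecture], reps: int,
                alpha: float = 0.05, seed=0,
                concentrations: Sequence[float] = BACKCROSS_CONCENTRATIONS,
                n_per_conc: int = 40, policy: str = "any-row"
                ) -> pd.DataFrame:
    """Monte-Carlo rejection rate of the monogenic test per architecture.

    For each replicate a backcross screen is simulated under each
    architecture with a paired per-replicate seed; expected mortalities are
    the exact (a + b)/2 of the generating model's F1 and SS strains, so
    under a one-locus truth the per-row test is calibrated and the
    experiment-wise rate approaches ``1 - (1 - alpha)^k_rows``. Returns one
    row per architecture with its rejection rate.
    """
    if reps < 100:
        raise ContractError("reps must be >= 100 for a stable rate")
    recs = []
    for name, arch in architectures.items():
        rejected = 0
        for rep in range(reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=(int(seed), rep)))
            rows = _backcross_rows_exact_expectation(
                arch, concentrations, n_per_conc, rng)
            res = monogenic_test(rows, alpha=alpha, policy=policy)
            rejected += int(res.rejected)
        recs.append({"architecture": name, "n_loci": arch.n_loci,
                     "reps": reps, "rejection_rate": rejected / reps})
    return pd.DataFrame(recs)
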