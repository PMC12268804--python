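"""Genetic architectures of insecticide tolerance and Mendelian crosses.

The tolerance model underlying every simulated bioassay: an individual's
log10 tolerance (its log10 LC50) is a baseline susceptible value plus
additive per-locus contributions of resistance (R) alleles, with a
within-locus dominance coefficient h for heterozygous loci. Mortality at
concentration c is ``Phi(beta * (log10 c - tolerance))`` with a common
probit slope beta. One locus with h derived from a target Stone's D
reproduces a monogenic study strain set; k equal-effect loci preserving the
parental endpoint LC50s realise the polygenic alternative.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats

from .errors import ContractError


@dataclass(frozen=True)
class Genotype:
    """Per-locus counts of the R allele, each in {0, 1, 2}, fixed order."""
    counts: Tuple[int, ...]

    def __post_init__(self):
        if not self.counts:
            raise ContractError("genotype needs at least one locus")
        if any(c not in (0, 1, 2) for c in self.counts):
            raise ContractError(f"allele counts must be 0/1/2: {self.counts}")

    @property
    def n_loci(self) -> int:
        return len(self.counts)

    @property
    def n_r_alleles(self) -> int:
        return sum(self.counts)

    @classmethod
    def homozygous_s(cls, k: int) -> "Genotype":
        return cls((0,) * k)

    @classmethod
    def homozygous_r(cls, k: int) -> "Genotype":
        return cls((2,) * k)

    @classmethod
    def heterozygous(cls, k: int) -> "Genotype":
        return cls((1,) * k)


@dataclass
class GeneticArchitecture:
    """k-locus additive architecture of log10 tolerance.

    Parameters
    ----------
    n_loci : int
        Number of unlinked loci (k >= 1).
    x_ss, x_rr : float
        log10 tolerance (log10 LC50, μg a.i./mL) of the all-S and all-R
        homozygotes. The per-locus additive effect defaults to
        ``(x_rr - x_ss) / (2k)`` per R allele, so a homozygous R locus adds
        ``2 * effect`` and a heterozygous locus adds ``2 * h * effect``.
    h : float
        Within-locus dominance of tolerance in [0, 1]; h = 0.5 is additive.
        With equal effects, an all-heterozygous F1 has Stone's D = 2h - 1
        regardless of k.
    slope : float
        Common probit slope beta (probits per log10 μg/mL), > 0.
    effects : array, optional
        Per-locus additive effects; must sum to ``(x_rr - x_ss) / 2``.
    """
    n_loci: int
    x_ss: float
    x_rr: float
    h: float = 0.5
    slope: float = 1.5
    effects: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.n_loci < 1:
            raise ContractError("n_loci must be >= 1")
        if not 0.0 <= self.h <= 1.0:
            raise ContractError("h must be in [0, 1]")
        if self.slope <= 0:
            raise ContractError("slope must be positive")
        if self.effects is None:
            self.effects = np.full(self.n_loci,
                                   (self.x_rr - self.x_ss) / (2 * self.n_loci))
        else:
            self.effects = np.asarray(self.effects, float)
            if len(self.effects) != self.n_loci:
                raise ContractError("effects length must equal n_loci")
            if abs(2 * self.effects.sum() - (self.x_rr - self.x_ss)) > 1e-9:
                raise ContractError(
                    "effects must sum to (x_rr - x_ss)/2 so the all-R "
                    "genotype hits x_rr")

    @classmethod
    def from_lc50s(cls, lc50_ss: float, lc50_rr: float, slope: float = 1.5,
                   n_loci: int = 1, d_stone: Optional[float] = None,
                   h: Optional[float] = None,
                   effects: Optional[np.ndarray] = None
                   ) -> "GeneticArchitecture":
        """Build an architecture from parental LC50s.

        Pass either ``d_stone`` (the target degree of dominance of the F1;
        h = (D + 1) / 2) or ``h`` directly; default is additive (h = 0.5).
        """
        if lc50_ss <= 0 or lc50_rr <= 0:
            raise ContractError("LC50s must be positive")
        if d_stone is not None:
            if h is not None:
                raise ContractError("give d_stone or h, not both")
            if not -1.0 <= d_stone <= 1.0:
                raise ContractError("d_stone must be in [-1, 1]")
            h = (d_stone + 1.0) / 2.0
        return cls(n_loci=n_loci, x_ss=float(np.log10(lc50_ss)),
                   x_rr=float(np.log10(lc50_rr)), h=0.5 if h is None else h,
                   slope=slope, effects=effects)

    # -- phenotype ---------------------------------------------------------
    def tolerance(self, g: Genotype) -> float:
        """log10 tolerance of a genotype: x_ss + sum of locus contributions
        (2e for RR, 2he for RS, 0 for SS)."""
        if g.n_loci != self.n_loci:
            raise ContractError("genotype/architecture loci mismatch")
        w = np.array([2.0 if c == 2 else (2.0 * self.h if c == 1 else 0.0)
                      for c in g.counts])
        return float(self.x_ss + np.dot(w, self.effects))

    def mortality(self, g: Genotype, concentration) -> np.ndarray:
        """P(death) of a genotype at the given concentration(s)."""
        c = np.asarray(concentration, float)
        return stats.norm.cdf(self.slope * (np.log10(c) - self.tolerance(g)))

    def mixture_mortality(self, mix: Dict[Genotype, float], concentration
                          ) -> np.ndarray:
        """Expected mortality of a genotype mixture at concentration(s)."""
        c = np.atleast_1d(np.asarray(concentration, float))
        out = np.zeros_like(c)
        for g, f in mix.items():
            out += f * self.mortality(g, c)
        return out if out.size > 1 else float(out[0])


def tolerance_of_genotype(arch: GeneticArchitecture, g: Genotype) -> float:
    return arch.tolerance(g)


def heterozygote_lc_from_dominance(d: float, lc_rr: float, lc_ss: float
                                   ) -> float:
    """Place the F1 LC50 from a target Stone's D (exact inverse of the
    Stone statistic): ``XF = XS + (D + 1)(XR - XS)/2``, returned as
    ``10**XF``."""
    if not -1.0 <= d <= 1.0:
        raise ContractError("D must be in [-1, 1]")
    if lc_rr <= 0 or lc_ss <= 0:
        raise ContractError("LC50s must be positive")
    if lc_rr == lc_ss:
        raise ContractError("parental LC50s must differ")
    xs, xr = np.log10(lc_ss), np.log10(lc_rr)
    return float(10.0 ** (xs + (d + 1.0) * (xr - xs) / 2.0))


# ---------------------------------------------------------------------------
# crosses
# ---------------------------------------------------------------------------
def _locus_offspring_dist(c1: int, c2: int) -> Dict[int, float]:
    """Offspring R-count distribution at one locus from parental counts."""
    p1, p2 = c1 / 2.0, c2 / 2.0
    return {
        0: (1 - p1) * (1 - p2),
        1: p1 * (1 - p2) + (1 - p1) * p2,
        2: p1 * p2,
    }


def cross_distribution(p1: Genotype, p2: Genotype
                       ) -> Dict[Genotype, float]:
    """Exact offspring genotype distribution (independent loci, enumerated).

    Limited to k <= 10 loci (3^k genotype classes); zero-probability
    classes are pruned.
    """
    if p1.n_loci != p2.n_loci:
        raise ContractError("parents must share the locus set")
    k = p1.n_loci
    if k > 10:
        raise ContractError("exact enumeration limited to k <= 10 loci")
    per_locus = [_locus_offspring_dist(a, b)
                 for a, b in zip(p1.counts, p2.counts)]
    dist: Dict[Genotype, float] = {}
    for combo in itertools.product(*(d.items() for d in per_locus)):
        pr = 1.0
        counts = []
        for c, w in combo:
            pr *= w
            counts.append(c)
        if pr > 0.0:
            g = Genotype(tuple(counts))
            dist[g] = dist.get(g, 0.0) + pr
    return dist


def make_cross(p1: Genotype, p2: Genotype, n_offspring: int = 0,
               seed=None) -> Tuple[List[Genotype], Dict[Genotype, float]]:
    """Mendelian cross: sampled offspring plus the exact distribution.

    Loci segregate independently; each parent transmits R at a locus with
    probability (allele count)/2. Returns ``(offspring, exact_dist)``;
    with ``n_offspring == 0`` only the exact distribution is populated.
    """
    dist = cross_distribution(p1, p2)
    offspring: List[Genotype] = []
    if n_offspring > 0:
        rng = np.random.default_rng(seed)
        k = p1.n_loci
        a1 = rng.random((n_offspring, k)) < np.array(p1.counts) / 2.0
        a2 = rng.random((n_offspring, k)) < np.array(p2.counts) / 2.0
        counts = a1.astype(int) + a2.astype(int)
        offspring = [Genotype(tuple(row)) for row in counts]
    return offspring, dist
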