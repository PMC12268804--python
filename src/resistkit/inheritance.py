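"""Dominance-of-resistance statistics and the backcross monogenic test.

Two classical dominance measures for insecticide resistance:

* Stone's degree of dominance on the log10 LC50 scale,
  ``D = (2*XF - XR - XS) / (XR - XS)`` with X = log10(LC50) of the F1
  heterozygotes (XF), resistant (XR) and susceptible (XS) parents.
  D = 1 is completely dominant resistance, D = -1 completely recessive.
* Bourguet's dose-specific dominance on the mortality scale,
  ``D = (M_RS - M_SS) / (M_RR - M_SS)`` from the three genotype
  mortalities at one concentration; evaluated along a concentration grid
  it yields the dominance-level (DML) curve, and at a field rate it is the
  "functional dominance" that decides whether heterozygotes survive a
  realistic application.

The monogenic-inheritance test compares observed backcross mortality at
each concentration against the Mendelian expectation ``p = (a + b) / 2``
(a, b = mortalities of the heterozygous and susceptible parent strains;
the backcross segregates 1:1 under one locus) with the chi-square
``(Ni - p*ni)^2 / (p*q*ni)``, df = 1. Rejection at any concentration is
evidence against monogenic (for polygenic) control.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import ProbitFit
from .errors import ContractError, UndefinedStatisticError

# ---------------------------------------------------------------------------
# dominance
# ---------------------------------------------------------------------------
_CLASS_TOL = 0.005


def classify_dominance(d: float) -> str:
    """Map a dominance value to its categorical label.

    Values within 0.005 of +-1 are called complete; otherwise the sign
    decides the incomplete category, with D = 0 labelled as the additive
    midpoint.
    """
    if not np.isfinite(d):
        raise ContractError("D must be finite")
    if abs(d - 1.0) <= _CLASS_TOL:
        return "complete dominant"
    if abs(d + 1.0) <= _CLASS_TOL:
        return "complete recessive"
    if d == 0.0:
        return "codominant/additive midpoint"
    return "incomplete dominant" if d > 0 else "incomplete recessive"


@dataclass
class DominanceEstimate:
    """A degree-of-dominance value with its method and inputs.

    ``method`` is ``"stone"`` (log10-LC50 scale) or ``"bourguet"``
    (mortality scale). Bourguet values outside [-1, 1] — possible when the
    heterozygote mortality falls outside the parental range — are returned
    unclamped with ``out_of_range=True``.
    """
    D: float
    method: str
    inputs: Dict[str, float]
    classification: str
    out_of_range: bool = False

    def rounded(self, ndigits: int = 2) -> float:
        return round(self.D, ndigits)


def dominance_stone(lc_rs: float, lc_rr: float, lc_ss: float
                    ) -> DominanceEstimate:
    """Stone's degree of dominance from the three genotype LC50s."""
    if min(lc_rs, lc_rr, lc_ss) <= 0:
        raise ContractError("LC50s must be positive")
    if lc_rr == lc_ss:
        raise UndefinedStatisticError(
            "parental LC50s are equal; Stone's D undefined")
    xf, xr, xs = np.log10([lc_rs, lc_rr, lc_ss])
    d = float((2 * xf - xr - xs) / (xr - xs))
    return DominanceEstimate(
        D=d, method="stone",
        inputs={"XF": float(xf), "XR": float(xr), "XS": float(xs)},
        classification=classify_dominance(d),
        out_of_range=not -1 - _CLASS_TOL <= d <= 1 + _CLASS_TOL)


def dominance_bourguet(m_rs: float, m_rr: float, m_ss: float
                       ) -> DominanceEstimate:
    """Bourguet's dominance level from genotype mortalities at one dose."""
    for name, m in (("m_rs", m_rs), ("m_rr", m_rr), ("m_ss", m_ss)):
        if not 0.0 <= m <= 1.0:
            raise ContractError(f"{name}={m} outside [0, 1]")
    if m_rr == m_ss:
        raise UndefinedStatisticError(
            "parental mortalities are equal; Bourguet's D undefined")
    d = float((m_rs - m_ss) / (m_rr - m_ss))
    return DominanceEstimate(
        D=d, method="bourguet",
        inputs={"MRS": m_rs, "MRR": m_rr, "MSS": m_ss},
        classification=classify_dominance(d),
        out_of_range=not -1.0 <= d <= 1.0)


def dml_curve(fit_ss: ProbitFit, fit_rs: ProbitFit, fit_rr: ProbitFit,
              concentrations: Sequence[float]) -> pd.DataFrame:
    """Bourguet dominance along a concentration grid, from fitted lines.

    Genotype mortalities are predicted from the three probit fits; each
    concentration where the parental predictions coincide is flagged
    ``undefined`` rather than dropped.
    """
    conc = np.asarray(concentrations, float)
    if (conc <= 0).any():
        raise ContractError("concentrations must be positive")
    rows = []
    for c in conc:
        m_ss = float(fit_ss.predict(c))
        m_rs = float(fit_rs.predict(c))
        m_rr = float(fit_rr.predict(c))
        if m_rr == m_ss:
            rows.append({"concentration_ug_ml": c, "D": np.nan,
                         "undefined": True, "m_ss": m_ss, "m_rs": m_rs,
                         "m_rr": m_rr})
            continue
        d = (m_rs - m_ss) / (m_rr - m_ss)
        rows.append({"concentration_ug_ml": c, "D": d, "undefined": False,
                     "m_ss": m_ss, "m_rs": m_rs, "m_rr": m_rr})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# backcross monogenic test
# ---------------------------------------------------------------------------
@dataclass
class BackcrossExpectation:
    """Expected backcross mortality at one concentration.

    Under one-locus Mendelian segregation the backcross to the susceptible
    parent is half heterozygotes (mortality ``a``) and half susceptibles
    (mortality ``b``), so the expected mortality is ``p = (a + b) / 2``.
    ``source`` records whether a and b are observed strain mortalities or
    probit-fitted values.
    """
    concentration: float
    a: float
    b: float
    p: float
    source: str = "observed"

    def __post_init__(self):
        for name, v in (("a", self.a), ("b", self.b)):
            if not 0.0 <= v <= 1.0:
                raise ContractError(f"{name}={v} outside [0, 1]")
        expected = (self.a + self.b) / 2.0
        if abs(self.p - expected) > 1e-12:
            raise ContractError("p must equal (a + b) / 2")

    @property
    def q(self) -> float:
        return 1.0 - self.p


def expected_backcross_mortality(a: float, b: float,
                                 concentration: float = float("nan"),
                                 source: str = "observed"
                                 ) -> BackcrossExpectation:
    """Mendelian one-locus expectation ``p = (a + b) / 2``."""
    return BackcrossExpectation(concentration=concentration, a=a, b=b,
                                p=(a + b) / 2.0, source=source)


@dataclass
class MonogenicTestResult:
    rows: pd.DataFrame
    verdict: str
    alpha: float
    policy: str = "any-row"

    @property
    def rejected(self) -> bool:
        return self.verdict == "monogenic rejected"


def monogenic_test(rows: Sequence[Mapping], alpha: float = 0.05,
                   policy: str = "any-row") -> MonogenicTestResult:
    """Per-concentration chi-square test of the monogenic null.

    Each row needs ``concentration``, ``n_dead`` (observed dead Ni),
    ``n_total`` (ni) and ``expected_p``. The statistic is
    ``(Ni - p*ni)^2 / (p*(1-p)*ni)``, df = 1 — the square of the one-sample
    proportion z statistic. Row-wise significance uses ``alpha`` with no
    multiplicity adjustment (mirroring the usual table presentation);
    the overall verdict policy is explicit:

    * ``"any-row"`` (default): reject monogenic inheritance if any row is
      significant;
    * ``"bonferroni"``: reject if any row is significant at ``alpha/k``.
    """
    if policy not in ("any-row", "bonferroni"):
        raise ContractError(f"unknown verdict policy {policy!r}")
    recs = []
    rows = list(rows)
    k = len(rows)
    if k == 0:
        raise ContractError("no rows to test")
    for r in rows:
        p = float(r["expected_p"])
        ni = int(r["n_total"])
        Ni = int(r["n_dead"])
        if not 0.0 < p < 1.0:
            raise UndefinedStatisticError(
                f"expected mortality p={p} gives zero binomial variance")
        if ni <= 0 or Ni < 0 or Ni > ni:
            raise ContractError(f"bad counts Ni={Ni}, ni={ni}")
        chi2 = (Ni - p * ni) ** 2 / (p * (1 - p) * ni)
        pval = float(stats.chi2.sf(chi2, 1))
        recs.append({"concentration_ug_ml": float(r.get("concentration",
                                                        np.nan)),
                     "n_dead": Ni, "n_total": ni, "expected_p": p,
                     "expected_dead": p * ni, "chi2": float(chi2),
                     "p_value": pval, "significant": pval < alpha})
    out = pd.DataFrame(recs)
    thr = alpha if policy == "any-row" else alpha / k
    reject = bool((out["p_value"] < thr).any())
    verdict = "monogenic rejected" if reject else "monogenic not rejected"
    return MonogenicTestResult(rows=out, verdict=verdict, alpha=alpha,
                               policy=policy)


def monogenic_from_tables(backcross, parent_het, parent_sus,
                          fit_het: Optional[ProbitFit] = None,
                          fit_sus: Optional[ProbitFit] = None,
                          alpha: float = 0.05, policy: str = "any-row"
                          ) -> MonogenicTestResult:
    """Assemble and run the monogenic test from bioassay tables.

    Expected mortalities use the parents' *observed* (replicate-pooled)
    mortality at the same tested concentration when available, otherwise
    probit-fitted values when fits are supplied; each row records its
    source.
    """
    bc = backcross.pooled()
    bc = bc[bc["concentration_ug_ml"] > 0]
    het = parent_het.pooled().set_index("concentration_ug_ml")
    sus = parent_sus.pooled().set_index("concentration_ug_ml")
    rows, sources = [], []
    for _, r in bc.iterrows():
        c = r["concentration_ug_ml"]
        vals = {}
        for label, pooled, fit in (("a", het, fit_het), ("b", sus, fit_sus)):
            if c in pooled.index:
                g = pooled.loc[c]
                vals[label] = float(g["n_dead"] / g["n_total"])
                vals[label + "_src"] = "observed"
            elif fit is not None:
                vals[label] = float(fit.predict(c))
                vals[label + "_src"] = "fitted"
            else:
                raise ContractError(
                    f"no parental mortality at {c} μg/mL and no fit supplied")
        exp = expected_backcross_mortality(
            vals["a"], vals["b"], concentration=c,
            source=f"a:{vals['a_src']},b:{vals['b_src']}")
        rows.append({"concentration": c, "n_dead": int(r["n_dead"]),
                     "n_total": int(r["n_total"]), "expected_p": exp.p})
        sources.append(exp.source)
    res = monogenic_test(rows, alpha=alpha, policy=policy)
    res.rows["source"] = sources
    return res


# ---------------------------------------------------------------------------
# functional dominance at field rates
# ---------------------------------------------------------------------------
@dataclass
class FunctionalDominanceResult:
    """Strain mortalities at one field-rate dose with pairwise comparisons.

    ``comparisons`` holds the pairwise two-proportion tests with single-step
    familywise-adjusted p-values; ``letters`` the compact letter display
    (strains sharing a letter are not significantly different);
    ``D_at_dose`` the Bourguet dominance of each heterozygous strain
    against the two parents at this dose.
    """
    dose: float
    mortality: pd.DataFrame
    comparisons: pd.DataFrame
    letters: Dict[str, str]
    D_at_dose: Dict[str, DominanceEstimate]
    alpha: float


def _two_proportion_z(d1, n1, d2, n2) -> Tuple[float, float]:
    p1, p2 = d1 / n1, d2 / n2
    pool = (d1 + d2) / (n1 + n2)
    var = pool * (1 - pool) * (1 / n1 + 1 / n2)
    if var == 0:
        return 0.0, 1.0
    z = (p1 - p2) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def _fisher_midp(d1, n1, d2, n2) -> float:
    """Two-sided mid-p of Fisher's exact test (small-count fallback)."""
    table = np.array([[d1, n1 - d1], [d2, n2 - d2]])
    res = stats.fisher_exact(table, alternative="two-sided")
    # mid-p: subtract half the point probability of the observed table
    pt = stats.hypergeom.pmf(d1, n1 + n2, d1 + d2, n1)
    return float(max(min(res.pvalue - 0.5 * pt, 1.0), 0.0))


def _tukey_adjust(z: float, k: int) -> float:
    """Single-step max-|z| (Tukey-type) adjustment for k groups.

    For large samples the studentized range with infinite df applies:
    ``p_adj = P(q_{k,inf} >= |z| * sqrt(2))``.
    """
    if k <= 2:
        return float(2 * stats.norm.sf(abs(z)))
    return float(stats.studentized_range.sf(abs(z) * np.sqrt(2.0), k, np.inf))


def _compact_letters(names: List[str], distinct: set) -> Dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``distinct`` holds frozensets {a, b} of significantly different pairs;
    strains sharing a letter are not significantly different.
    """
    groups: List[set] = [set(names)]
    for a, b in itertools.combinations(names, 2):
        if frozenset((a, b)) not in distinct:
            continue
        new_groups = []
        for g in groups:
            if a in g and b in g:
                ga, gb = g - {b}, g - {a}
                for cand in (ga, gb):
                    if not any(cand <= other for other in new_groups + groups
                               if other is not g and cand != other):
                        new_groups.append(cand)
            else:
                new_groups.append(g)
        # absorb subsets
        groups = []
        for g in new_groups:
            if not any(g < other for other in new_groups if other is not g):
                if g not in groups:
                    groups.append(g)
    # stable letter assignment by mean rank of members
    order = {n: i for i, n in enumerate(names)}
    groups.sort(key=lambda g: min(order[m] for m in g))
    letters = {n: "" for n in names}
    for i, g in enumerate(groups):
        for n in g:
            letters[n] += chr(ord("a") + i)
    return {n: "".join(sorted(v)) for n, v in letters.items()}


def functional_dominance(counts: Mapping[str, Tuple[int, int]], dose: float,
                         ss: str, rr: str,
                         het: Optional[Sequence[str]] = None,
                         alpha: float = 0.05) -> FunctionalDominanceResult:
    """Compare strain mortalities at one dose; dominance of each F1 strain.

    ``counts`` maps strain -> (n_dead, n_total). Pairwise two-proportion
    z-tests are adjusted single-step (max-|z|, Tukey-style); when any count
    or complement is below 5 the raw p-value falls back to a Fisher
    mid-p with a Sidak-style single-step adjustment. Letters follow the
    adjusted tests at ``alpha``.
    """
    names = list(counts)
    if len(names) < 2:
        raise ContractError("need at least two strains")
    for s, (d, n) in counts.items():
        if n <= 0:
            raise ContractError(f"strain {s} has no exposed insects")
        if not 0 <= d <= n:
            raise ContractError(f"strain {s}: bad counts {d}/{n}")
    k = len(names)
    ncomp = k * (k - 1) // 2
    mort = pd.DataFrame(
        [{"strain": s, "n_dead": d, "n_total": n, "mortality": d / n}
         for s, (d, n) in counts.items()])
    recs, distinct = [], set()
    for a, b in itertools.combinations(names, 2):
        d1, n1 = counts[a]
        d2, n2 = counts[b]
        small = min(d1, n1 - d1, d2, n2 - d2) < 5
        z, p_raw = _two_proportion_z(d1, n1, d2, n2)
        if small:
            p_raw = _fisher_midp(d1, n1, d2, n2)
            p_adj = 1.0 - (1.0 - p_raw) ** ncomp
            method = "fisher-midp/sidak"
        else:
            p_adj = _tukey_adjust(z, k)
            method = "z/tukey"
        p_adj = float(min(p_adj, 1.0))
        sig = p_adj < alpha
        if sig:
            distinct.add(frozenset((a, b)))
        recs.append({"strain_1": a, "strain_2": b, "z": z, "p_raw": p_raw,
                     "p_adj": p_adj, "method": method, "significant": sig})
    comparisons = pd.DataFrame(recs)
    # letters ordered by decreasing mortality, as usually displayed
    ordered = sorted(names, key=lambda s: -counts[s][0] / counts[s][1])
    letters = _compact_letters(ordered, distinct)
    d_at = {}
    m = {s: d / n for s, (d, n) in counts.items()}
    het = list(het) if het is not None else [s for s in names
                                             if s not in (ss, rr)]
    for h in het:
        if h not in counts:
            raise ContractError(f"heterozygous strain {h} not in counts")
        if m[rr] != m[ss]:
            d_at[h] = dominance_bourguet(m[h], m[rr], m[ss])
    return FunctionalDominanceResult(dose=dose, mortality=mort,
                                     comparisons=comparisons,
                                     letters=letters, D_at_dose=d_at,
                                     alpha=alpha)
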