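"""Quantal dose-response analysis with a probit link on log10 concentration.

The model is ``mortality = Phi(alpha + beta * log10(concentration))`` fitted
by maximum likelihood (binomial GLM, probit link). From a fit this module
derives lethal concentrations LC_p with delta-method confidence limits on
the log10-dose scale (the `dose.p` convention), resistance ratios with
lethal-dose-ratio confidence intervals, Pearson goodness of fit with the
classic heterogeneity-factor variance inflation, likelihood-ratio tests of
equality and parallelism between lines, and the diagnostic (discriminating)
dose used for resistance monitoring.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .bioassay import BioassayTable
from .errors import (ContractError, NonConvergenceError, SeparationError,
                     UndefinedStatisticError, UnidentifiableSlopeError)

Z95 = stats.norm.ppf(0.975)  # 1.959964...


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------
@dataclass
class ProbitFit:
    """Maximum-likelihood probit line for one strain x compound.

    ``intercept`` (probits) and ``slope`` (probits per log10 μg/mL) with the
    2x2 parameter covariance in (intercept, slope) order. ``heterogeneity``
    is Pearson chi2 / df; ``inflate`` records whether downstream variances
    are multiplied by it (goodness-of-fit p < 0.05, the classic probit
    overdispersion correction).
    """
    strain: str
    compound: str
    intercept: float
    slope: float
    slope_se: float
    cov: np.ndarray
    n_groups: int
    df: int
    pearson_chi2: float
    gof_p: float
    heterogeneity: float
    n_total: int
    loglik: float
    inflate: bool = False
    warnings: List[str] = field(default_factory=list)

    @property
    def var_scale(self) -> float:
        """Variance multiplier applied to delta-method variances."""
        return self.heterogeneity if self.inflate else 1.0

    def predict(self, concentration) -> np.ndarray:
        """Expected mortality at the given concentration(s) (μg a.i./mL)."""
        c = np.asarray(concentration, dtype=float)
        return stats.norm.cdf(self.intercept + self.slope * np.log10(c))


@dataclass
class LcEstimate:
    """A lethal concentration LC_p with delta-method limits.

    ``se_log10`` is the standard error of log10(dose); the 95% CI is
    ``10 ** (log10(dose) +- 1.96 * se_log10)``. Built from a bare point
    value (no fit), ``se_log10`` is None and the CI collapses to the point.
    """
    p: float
    dose: float
    se_log10: Optional[float]
    ci_low: float
    ci_high: float
    strain: Optional[str] = None
    compound: Optional[str] = None
    warnings: List[str] = field(default_factory=list)

    @classmethod
    def from_point(cls, dose: float, p: float = 0.5,
                   strain: Optional[str] = None,
                   compound: Optional[str] = None) -> "LcEstimate":
        """Wrap a published/rounded LC_p point value with no uncertainty."""
        if dose <= 0:
            raise ContractError("dose must be positive")
        return cls(p=p, dose=float(dose), se_log10=None, ci_low=float(dose),
                   ci_high=float(dose), strain=strain, compound=compound)


@dataclass
class RatioEstimate:
    """A resistance ratio RR = LC_p(resistant) / LC_p(susceptible)."""
    ratio: float
    ci_low: float
    ci_high: float
    method: str
    inputs_rounded: bool = False


@dataclass
class LineComparison:
    """Likelihood-ratio test of equality or parallelism between lines."""
    hypothesis: str
    chi2: float
    df: int
    p_value: float
    n_lines: int


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------
def _pool_line(table: BioassayTable, strain: Optional[str],
               compound: Optional[str]) -> pd.DataFrame:
    sub = table.subset(strain=strain, compound=compound)
    pooled = sub.pooled()
    pooled = pooled[pooled["concentration_ug_ml"] > 0]
    lines = pooled.groupby(["strain", "compound"]).ngroups
    if lines == 0:
        raise ContractError("no treated rows for the requested line")
    if lines > 1:
        raise ContractError(
            "table holds several strain/compound lines; pass strain= and "
            "compound= to select one")
    return pooled.sort_values("concentration_ug_ml").reset_index(drop=True)


def _check_degenerate(pooled: pd.DataFrame) -> None:
    if pooled["concentration_ug_ml"].nunique() < 2:
        raise ContractError(
            "need >= 2 distinct positive concentrations to fit")
    prop = (pooled["n_dead"] / pooled["n_total"]).to_numpy()
    if np.allclose(prop, prop[0]):
        raise UnidentifiableSlopeError(
            f"all concentration groups show identical mortality "
            f"({prop[0]:.3f}); the slope is unidentifiable")
    # perfect 0 -> 1 step over sorted concentrations: MLE slope diverges
    extreme = np.isin(prop, (0.0, 1.0)).all()
    if extreme and np.all(np.diff(prop) >= 0) and prop[0] == 0.0 \
            and prop[-1] == 1.0:
        raise SeparationError(
            "complete separation: mortality steps perfectly from 0% to 100% "
            "across concentrations; the probit MLE does not exist. Add "
            "concentrations giving intermediate mortality.")


def _glm_probit(endog: np.ndarray, exog: np.ndarray):
    model = sm.GLM(endog, exog,
                   family=sm.families.Binomial(sm.families.links.Probit()))
    try:
        res = model.fit(maxiter=100, tol=1e-8)
    except Exception as e:  # pragma: no cover - statsmodels internal failure
        raise NonConvergenceError(f"IRLS failed: {e}") from None
    if not res.converged:
        raise NonConvergenceError("IRLS did not converge in 100 iterations")
    return res


def fit_probit(table: BioassayTable, strain: Optional[str] = None,
               compound: Optional[str] = None) -> ProbitFit:
    """Fit ``mortality = Phi(alpha + beta * log10 c)`` for one line.

    Control rows (concentration 0) never enter the likelihood. Replicate
    rows are pooled per concentration (the binomial likelihood is identical
    either way). A non-positive fitted slope attaches a warning rather than
    failing: a flat or declining line is a data problem the caller should
    see, not a crash.
    """
    pooled = _pool_line(table, strain, compound)
    _check_degenerate(pooled)
    x = np.log10(pooled["concentration_ug_ml"].to_numpy())
    n = pooled["n_total"].to_numpy(dtype=float)
    dead = pooled["n_dead"].to_numpy(dtype=float)
    exog = sm.add_constant(x)
    res = _glm_probit(np.column_stack([dead, n - dead]), exog)
    alpha, beta = res.params
    cov = np.asarray(res.cov_params())
    slope_se = float(np.sqrt(cov[1, 1]))
    warns = []
    if beta <= 0:
        warns.append("fitted slope <= 0: mortality does not increase with "
                     "concentration")
    # Pearson GOF over concentration groups
    phat = stats.norm.cdf(alpha + beta * x)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.sum((dead - n * phat) ** 2 /
                            (n * phat * (1 - phat))))
    g = len(pooled)
    dof = g - 2
    if dof > 0:
        gof_p = float(stats.chi2.sf(chi2, dof))
        het = chi2 / dof
    else:
        gof_p, het = float("nan"), float("nan")
    inflate = bool(dof > 0 and gof_p < 0.05 and het > 1.0)
    s = pooled["strain"].iloc[0]
    c = pooled["compound"].iloc[0]
    return ProbitFit(strain=s, compound=c, intercept=float(alpha),
                     slope=float(beta), slope_se=slope_se, cov=cov,
                     n_groups=g, df=dof, pearson_chi2=chi2, gof_p=gof_p,
                     heterogeneity=het, n_total=int(n.sum()),
                     loglik=float(res.llf), inflate=inflate, warnings=warns)


def goodness_of_fit(fit: ProbitFit, table: Optional[BioassayTable] = None
                    ) -> dict:
    """Pearson chi-square of the fitted line over concentration groups.

    ``df = groups - 2``; heterogeneity = chi2/df. When the fit's p-value is
    below 0.05 the fit carries ``inflate=True`` and downstream delta-method
    variances are multiplied by the heterogeneity factor.

    If ``table`` is given the statistic is recomputed from it (duplicate
    concentrations pooled first); otherwise the values stored at fit time
    are returned.
    """
    if table is not None:
        pooled = _pool_line(table, fit.strain, fit.compound)
        x = np.log10(pooled["concentration_ug_ml"].to_numpy())
        n = pooled["n_total"].to_numpy(dtype=float)
        dead = pooled["n_dead"].to_numpy(dtype=float)
        phat = stats.norm.cdf(fit.intercept + fit.slope * x)
        chi2 = float(np.sum((dead - n * phat) ** 2 / (n * phat * (1 - phat))))
        dof = len(pooled) - 2
    else:
        chi2, dof = fit.pearson_chi2, fit.df
    if dof <= 0:
        raise UndefinedStatisticError(
            f"goodness of fit undefined with {dof} degrees of freedom")
    p = float(stats.chi2.sf(chi2, dof))
    return {"chi2": chi2, "df": dof, "p_value": p,
            "heterogeneity": chi2 / dof, "inflated": bool(p < 0.05)}


def pearson_chi2(observed_dead: Sequence[float], n: Sequence[float],
                 expected_p: Sequence[float]) -> float:
    """Pearson chi-square of binomial counts against expected proportions."""
    dead = np.asarray(observed_dead, float)
    n = np.asarray(n, float)
    p = np.asarray(expected_p, float)
    return float(np.sum((dead - n * p) ** 2 / (n * p * (1 - p))))


# ---------------------------------------------------------------------------
# lethal concentrations and ratios
# ---------------------------------------------------------------------------
def estimate_lc(fit: ProbitFit, p: float = 0.5) -> LcEstimate:
    """LC_p with a delta-method CI on the log10-dose scale.

    ``log10 dose = (Phi^-1(p) - alpha) / beta``; its variance comes from the
    parameter covariance through the gradient ``(-1/beta, -log10dose/beta)``,
    scaled by the heterogeneity factor when the fit is overdispersed.
    """
    if not 0.0 < p < 1.0:
        raise ContractError("p must be in (0, 1)")
    if fit.slope == 0:
        raise ContractError("slope is zero; LC_p undefined")
    z = stats.norm.ppf(p)
    theta = (z - fit.intercept) / fit.slope
    grad = np.array([-1.0 / fit.slope, -theta / fit.slope])
    var = float(grad @ fit.cov @ grad) * fit.var_scale
    se = float(np.sqrt(max(var, 0.0)))
    dose = 10.0 ** theta
    warns = []
    if fit.slope < 0 and p > 0.5:
        warns.append("extrapolating a declining mortality line above LC50")
    return LcEstimate(p=p, dose=dose, se_log10=se,
                      ci_low=10.0 ** (theta - Z95 * se),
                      ci_high=10.0 ** (theta + Z95 * se),
                      strain=fit.strain, compound=fit.compound,
                      warnings=warns)


def resistance_ratio(lc_r: LcEstimate, lc_s: LcEstimate) -> RatioEstimate:
    """RR = LC_p(resistant) / LC_p(susceptible), lethal-dose-ratio CI.

    With independent fits the log10 ratio has standard error
    ``sqrt(se_R^2 + se_S^2)`` and the CI is ``ratio * 10^(+-1.96 se)``.
    Both estimates must be at the same quantile and (when recorded) for the
    same compound. If either input lacks a standard error (a published,
    rounded point value) the ratio is returned with a degenerate CI and an
    ``inputs_rounded`` flag.
    """
    if abs(lc_r.p - lc_s.p) > 1e-9:
        raise ContractError(
            f"LC quantiles differ ({lc_r.p} vs {lc_s.p})")
    if (lc_r.compound is not None and lc_s.compound is not None
            and lc_r.compound != lc_s.compound):
        raise ContractError(
            f"compounds differ ({lc_r.compound} vs {lc_s.compound})")
    ratio = lc_r.dose / lc_s.dose
    if lc_r.se_log10 is None or lc_s.se_log10 is None:
        return RatioEstimate(ratio=ratio, ci_low=ratio, ci_high=ratio,
                             method="point (no uncertainty)",
                             inputs_rounded=True)
    se = float(np.hypot(lc_r.se_log10, lc_s.se_log10))
    return RatioEstimate(ratio=ratio,
                         ci_low=ratio * 10.0 ** (-Z95 * se),
                         ci_high=ratio * 10.0 ** (Z95 * se),
                         method="lethal-dose-ratio (independent fits)")


def diagnostic_dose(fit: ProbitFit, table: Optional[BioassayTable] = None,
                    p: float = 0.99) -> float:
    """Discriminating dose: upper 95% confidence limit of the susceptible
    strain's LC99 (or LC_p). With a zero-variance fit this equals the point
    estimate."""
    return estimate_lc(fit, p).ci_high


# ---------------------------------------------------------------------------
# between-line hypothesis tests
# ---------------------------------------------------------------------------
def compare_lines(tables: Sequence[Union[BioassayTable, Tuple]],
                  hypothesis: str = "equality") -> LineComparison:
    """Likelihood-ratio test between probit lines.

    ``hypothesis='equality'`` constrains all lines to one (intercept, slope);
    ``'parallelism'`` constrains the slope only, leaving intercepts free.
    The statistic is 2*(sum of separate-fit log-likelihoods minus the
    constrained log-likelihood), referred to chi-square with
    ``2*(L-1)`` (equality) or ``L-1`` (parallelism) degrees of freedom.

    Each element of ``tables`` is a single-line :class:`BioassayTable` or a
    ``(table, strain, compound)`` triple selecting one line.
    """
    if hypothesis not in ("equality", "parallelism"):
        raise ContractError(f"unknown hypothesis {hypothesis!r}")
    if len(tables) < 2:
        raise ContractError("need at least two lines to compare")
    xs, ns, deads, idx = [], [], [], []
    ll_full = 0.0
    compounds = set()
    for i, t in enumerate(tables):
        if isinstance(t, tuple):
            tab, s, c = t
        else:
            tab, s, c = t, None, None
        pooled = _pool_line(tab, s, c)
        _check_degenerate(pooled)
        compounds.add(pooled["compound"].iloc[0])
        x = np.log10(pooled["concentration_ug_ml"].to_numpy())
        n = pooled["n_total"].to_numpy(float)
        dead = pooled["n_dead"].to_numpy(float)
        res = _glm_probit(np.column_stack([dead, n - dead]),
                          sm.add_constant(x))
        ll_full += float(res.llf)
        xs.append(x); ns.append(n); deads.append(dead)
        idx.append(np.full(len(x), i))
    if len(compounds) > 1:
        raise ContractError(f"lines span several compounds: {compounds}")
    L = len(tables)
    x = np.concatenate(xs); n = np.concatenate(ns)
    dead = np.concatenate(deads); line = np.concatenate(idx)
    endog = np.column_stack([dead, n - dead])
    if hypothesis == "equality":
        exog = sm.add_constant(x)
        dof = 2 * (L - 1)
    else:  # parallelism: per-line intercepts, common slope
        dummies = np.zeros((len(x), L))
        dummies[np.arange(len(x)), line.astype(int)] = 1.0
        exog = np.column_stack([dummies, x])
        dof = L - 1
    res0 = _glm_probit(endog, exog)
    chi2 = max(0.0, 2.0 * (ll_full - float(res0.llf)))
    return LineComparison(hypothesis=hypothesis, chi2=chi2, df=dof,
                          p_value=float(stats.chi2.sf(chi2, dof)),
                          n_lines=L)
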