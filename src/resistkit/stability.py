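"""Resistance-stability analysis at a diagnostic dose across generations.

Input: bioassay counts at a single diagnostic concentration, scored per
generation for several treatments (founding R:S proportions). Output: per
generation x treatment survival with binomial confidence limits, pairwise
within-generation comparisons with compact letter groups (the same
two-proportion engine as the functional-dominance analysis), and a
per-treatment trend summary (logistic regression of survival on
generation). Declining survival at the diagnostic dose over generations
without exposure is the signature of an unstable resistance trait, i.e. a
fitness cost.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .bioassay import BioassayTable
from .errors import ContractError
from .inheritance import functional_dominance


@dataclass
class StabilityResult:
    survival: pd.DataFrame
    comparisons: pd.DataFrame
    trends: pd.DataFrame
    gaps: List[dict]
    diagnostic_dose: float
    alpha: float


def stability_analysis(table: BioassayTable, diagnostic_dose: float,
                       alpha: float = 0.05) -> StabilityResult:
    """Per-generation survival comparison at the diagnostic dose.

    ``table`` rows must carry the ``generation`` column; the ``strain``
    column labels the treatment. Rows at other concentrations are ignored.
    Generations missing for a treatment are flagged in ``gaps``, never
    interpolated.
    """
    df = table.df
    df = df[df["concentration_ug_ml"] == diagnostic_dose].copy()
    if df.empty:
        raise ContractError(
            f"no rows at the diagnostic dose {diagnostic_dose} μg/mL")
    if df["generation"].isna().any():
        raise ContractError("stability rows must carry a generation")
    df["generation"] = df["generation"].astype(int)
    generations = sorted(df["generation"].unique())
    if len(generations) < 2:
        raise ContractError("need counts from at least two generations")
    treatments = list(df["strain"].unique())

    pooled = (df.groupby(["strain", "generation"])[["n_total", "n_dead"]]
              .sum().reset_index())
    surv_rows = []
    for _, r in pooled.iterrows():
        alive = r["n_total"] - r["n_dead"]
        lo, hi = proportion_confint(alive, r["n_total"], alpha=alpha,
                                    method="wilson")
        surv_rows.append({"strain": r["strain"],
                          "generation": int(r["generation"]),
                          "n_total": int(r["n_total"]),
                          "n_survived": int(alive),
                          "survival": alive / r["n_total"],
                          "ci_low": float(lo), "ci_high": float(hi)})
    survival = pd.DataFrame(surv_rows).sort_values(
        ["generation", "strain"]).reset_index(drop=True)

    # within-generation pairwise comparisons + letters, reusing the
    # functional-dominance two-proportion engine on survival counts
    comp_rows = []
    letters_by_gen: Dict[int, Dict[str, str]] = {}
    for gen in generations:
        g = survival[survival["generation"] == gen]
        counts = {r["strain"]: (r["n_survived"], r["n_total"])
                  for _, r in g.iterrows()}
        if len(counts) < 2:
            letters_by_gen[gen] = {s: "a" for s in counts}
            continue
        ss, rr = list(counts)[0], list(counts)[1]  # roles unused here
        res = functional_dominance(counts, dose=diagnostic_dose,
                                   ss=ss, rr=rr, het=[], alpha=alpha)
        letters_by_gen[gen] = res.letters
        c = res.comparisons.copy()
        c.insert(0, "generation", gen)
        comp_rows.append(c)
    comparisons = (pd.concat(comp_rows, ignore_index=True)
                   if comp_rows else pd.DataFrame(
                       columns=["generation", "strain_1", "strain_2", "z",
                                "p_raw", "p_adj", "method", "significant"]))
    survival["letters"] = [
        letters_by_gen.get(r["generation"], {}).get(r["strain"], "")
        for _, r in survival.iterrows()]

    # per-treatment trend: logistic regression of survival on generation
    trend_rows = []
    gaps = []
    for s in treatments:
        g = survival[survival["strain"] == s].sort_values("generation")
        missing = sorted(set(generations) - set(g["generation"]))
        if missing:
            gaps.append({"strain": s, "missing_generations": missing})
        if len(g) < 2:
            trend_rows.append({"strain": s, "slope": np.nan,
                               "p_value": np.nan, "direction": "undefined",
                               "monotone_decreasing": False})
            continue
        endog = np.column_stack([g["n_survived"],
                                 g["n_total"] - g["n_survived"]])
        exog = sm.add_constant(g["generation"].to_numpy(float))
        try:
            import warnings
            with warnings.catch_warnings():
                # all-dead / all-alive treatments separate perfectly; the
                # trend is then flat and the slope p-value is ~1, which is
                # the right answer — silence the fit's complaint
                warnings.simplefilter("ignore")
                fit = sm.GLM(endog, exog,
                             family=sm.families.Binomial()).fit()
            slope = float(fit.params[1])
            pval = float(fit.pvalues[1])
        except Exception:
            slope, pval = np.nan, np.nan
        direction = ("decreasing" if slope < 0 and pval < alpha else
                     "increasing" if slope > 0 and pval < alpha else
                     "no significant trend")
        mono = bool(np.all(np.diff(g["survival"].to_numpy()) <= 0))
        trend_rows.append({"strain": s, "slope": slope, "p_value": pval,
                           "direction": direction,
                           "monotone_decreasing": mono})
    trends = pd.DataFrame(trend_rows)
    return StabilityResult(survival=survival, comparisons=comparisons,
                           trends=trends, gaps=gaps,
                           diagnostic_dose=diagnostic_dose, alpha=alpha)
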