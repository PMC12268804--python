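"""Report assembly: orchestrates the analyses into table-shaped outputs.

The report mirrors the layout of published resistance tables: one row per
fitted line with n, slope +- SE, chi2 (df), p, LC50 (95% CI) and the
resistance ratio against a reference strain, plus inheritance, monogenic
and stability sections when requested. Numbers are kept at full precision
in the JSON report and rounded to 2 decimals in the CSV mirrors.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bioassay import BioassayTable, abbott_correct
from .dose_response import (LcEstimate, ProbitFit, compare_lines, estimate_lc,
                            fit_probit, resistance_ratio)
from .errors import ContractError
from .inheritance import dml_curve, dominance_stone, monogenic_from_tables
from .stability import stability_analysis

REPORT_COLUMNS = ["strain", "compound", "n", "slope", "slope_se", "chi2",
                  "df", "p", "lc50", "lc50_lo", "lc50_hi", "rr", "rr_lo",
                  "rr_hi"]


@dataclass
class AnalysisReport:
    """Sections keyed by analysis name, plus run metadata.

    Metadata records the tool version, seeds, and the analysis decisions in
    effect (Abbott correction, heterogeneity inflation, CI method) so that
    printed-table comparisons are auditable.
    """
    metadata: dict
    sections: Dict[str, object] = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        def default(o):
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="records")
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        payload = {"metadata": self.metadata, "sections": self.sections}
        return json.dumps(payload, default=default, indent=indent,
                          sort_keys=True, allow_nan=True)


def dose_response_report(table: BioassayTable,
                         reference_strain: Optional[str] = None,
                         compound: Optional[str] = None,
                         p: float = 0.5, abbott: bool = False
                         ) -> pd.DataFrame:
    """Fit every (strain, compound) line and tabulate LC50s and RRs.

    The RR column divides each line's LC_p by the reference strain's for
    the same compound, through :func:`resistance_ratio` (no independent
    arithmetic path). With no reference strain the RR columns are NaN.
    """
    if abbott:
        table = abbott_correct(table)
    sub = table if compound is None else table.subset(compound=compound)
    fits: Dict[tuple, ProbitFit] = {}
    lcs: Dict[tuple, LcEstimate] = {}
    for (s, c), g in sub.groups():
        fit = fit_probit(g)
        fits[(s, c)] = fit
        lcs[(s, c)] = estimate_lc(fit, p)
    rows = []
    for (s, c), fit in fits.items():
        lc = lcs[(s, c)]
        row = {"strain": s, "compound": c, "n": fit.n_total,
               "slope": fit.slope, "slope_se": fit.slope_se,
               "chi2": fit.pearson_chi2, "df": fit.df, "p": fit.gof_p,
               "lc50": lc.dose, "lc50_lo": lc.ci_low, "lc50_hi": lc.ci_high,
               "rr": np.nan, "rr_lo": np.nan, "rr_hi": np.nan}
        if reference_strain is not None and s != reference_strain:
            ref = lcs.get((reference_strain, c))
            if ref is None:
                raise ContractError(
                    f"reference strain {reference_strain!r} has no fitted "
                    f"line for compound {c!r}")
            rr = resistance_ratio(lc, ref)
            row.update({"rr": rr.ratio, "rr_lo": rr.ci_low,
                        "rr_hi": rr.ci_high})
        rows.append(row)
    return pd.DataFrame(rows)[REPORT_COLUMNS]


def inheritance_report(table: BioassayTable, ss: str, rr: str,
                       het: Sequence[str],
                       dml_concentrations: Optional[Sequence[float]] = None
                       ) -> dict:
    """Stone's D per heterozygous strain, reciprocal-line equality and
    parallelism tests, and the Bourguet dominance (DML) curve."""
    needed = [ss, rr, *het]
    for s in needed:
        if (table.df["strain"] == s).sum() == 0:
            raise ContractError(f"strain {s!r} absent from the table; "
                                "dominance analysis needs SS, RR and F1 "
                                "strains")
    fits = {s: fit_probit(table.subset(strain=s)) for s in needed}
    lc = {s: estimate_lc(fits[s], 0.5) for s in needed}
    stone = {}
    for h in het:
        d = dominance_stone(lc[h].dose, lc[rr].dose, lc[ss].dose)
        stone[h] = {"D": d.D, "D_rounded": d.rounded(),
                    "classification": d.classification}
    section = {"lc50": {s: lc[s].dose for s in needed},
               "stone_dominance": stone}
    if len(het) >= 2:
        tabs = [table.subset(strain=h) for h in het[:2]]
        eq = compare_lines(tabs, "equality")
        par = compare_lines(tabs, "parallelism")
        section["reciprocal_tests"] = {
            "equality": {"chi2": eq.chi2, "df": eq.df, "p": eq.p_value},
            "parallelism": {"chi2": par.chi2, "df": par.df,
                            "p": par.p_value}}
    if dml_concentrations is None:
        dml_concentrations = np.geomspace(
            lc[ss].dose, lc[rr].dose, 25)
    curve = dml_curve(fits[ss], fits[het[0]], fits[rr], dml_concentrations)
    section["dml_curve"] = curve
    return section


def run_pipeline(config: dict, seed: Optional[int] = None) -> AnalysisReport:
    """Run the analyses requested in ``config`` and assemble a report.

    Config keys:

    * ``input``: path to a bioassay CSV (or ``table``: a BioassayTable);
    * ``analyses``: list drawn from {"dose_response", "inheritance",
      "monogenic", "stability"};
    * ``reference_strain``, ``compound``: for the dose-response/RR table;
    * ``ss``, ``rr``, ``het``: strain labels for the inheritance section;
    * ``backcrosses``: mapping backcross strain -> heterozygous parent
      strain for the monogenic section;
    * ``diagnostic_dose``: for the stability section;
    * ``abbott``: bool, control-mortality correction (default off);
    * ``alpha``: significance level (default 0.05).

    The report is deterministic given fixed inputs and seed.
    """
    if "table" in config:
        table = config["table"]
    elif "input" in config:
        table = BioassayTable.from_csv(config["input"])
    else:
        raise ContractError("config needs 'input' (CSV path) or 'table'")
    analyses = config.get("analyses", ["dose_response"])
    alpha = float(config.get("alpha", 0.05))
    abbott = bool(config.get("abbott", False))
    meta = {"tool": "resistkit", "version": __version__, "seed": seed,
            "alpha": alpha,
            "decisions": {"abbott": abbott,
                          "ci_method": "delta method on log10 dose",
                          "rr_ci_method": "lethal-dose-ratio",
                          "heterogeneity_inflation": "when GOF p < 0.05"}}
    report = AnalysisReport(metadata=meta)
    if "dose_response" in analyses:
        report.sections["dose_response"] = dose_response_report(
            table, reference_strain=config.get("reference_strain"),
            compound=config.get("compound"), abbott=abbott)
    if "inheritance" in analyses:
        report.sections["inheritance"] = inheritance_report(
            table, ss=config["ss"], rr=config["rr"],
            het=list(config.get("het", [])))
    if "monogenic" in analyses:
        ss = config["ss"]
        sus_table = table.subset(strain=ss)
        fit_sus = fit_probit(sus_table)
        out = {}
        for bc_strain, het_parent in dict(config["backcrosses"]).items():
            het_table = table.subset(strain=het_parent)
            res = monogenic_from_tables(
                table.subset(strain=bc_strain), het_table, sus_table,
                fit_het=fit_probit(het_table), fit_sus=fit_sus,
                alpha=alpha)
            out[bc_strain] = {"verdict": res.verdict, "rows": res.rows}
        report.sections["monogenic"] = out
    if "stability" in analyses:
        res = stability_analysis(table, float(config["diagnostic_dose"]),
                                 alpha=alpha)
        report.sections["stability"] = {
            "survival": res.survival, "comparisons": res.comparisons,
            "trends": res.trends, "gaps": res.gaps}
    return report


def write_report(report: AnalysisReport, out_dir, fmt: str = "json") -> list:
    """Write the report to ``out_dir``; returns the paths written.

    ``fmt`` is ``"json"`` (full precision, deterministic) or ``"csv"``
    (one file per tabular section, display rounding to 2 decimals).
    """
    import pathlib
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if fmt == "json":
        path = out_dir / "report.json"
        path.write_text(report.to_json())
        written.append(path)
    elif fmt == "csv":
        for name, section in report.sections.items():
            frames = ({name: section} if isinstance(section, pd.DataFrame)
                      else {f"{name}_{k}": v for k, v in section.items()
                            if isinstance(v, pd.DataFrame)})
            for fname, frame in frames.items():
                path = out_dir / f"{fname}.csv"
                frame.round(2).to_csv(path, index=False)
                written.append(path)
    else:
        raise ContractError(f"unknown format {fmt!r}")
    return written
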