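"""Validated bioassay count tables and control-mortality correction.

A bioassay record is one Petri dish (or pooled set of dishes): a strain, a
compound, a concentration in μg a.i./mL, the number of insects exposed and
the number dead after the scoring interval. Concentration 0 marks untreated
controls. Tables are thin, validated wrappers around a pandas DataFrame with
a fixed schema shared by the whole package and its CSV interchange format.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ContractError, ParseError, RejectedAssayError

#: Canonical column order of the bioassay CSV interchange format.
COLUMNS = [
    "strain",
    "compound",
    "concentration_ug_ml",
    "n_total",
    "n_dead",
    "replicate",
    "generation",
]
REQUIRED = COLUMNS[:5]
OPTIONAL = COLUMNS[5:]


class BioassayTable:
    """Replicated dead/exposed counts per strain x compound x concentration.

    Parameters
    ----------
    df : pandas.DataFrame
        Must carry the required columns ``strain, compound,
        concentration_ug_ml, n_total, n_dead``; ``replicate`` and
        ``generation`` are optional and added (as missing) when absent.
    meta : dict, optional
        Free-form provenance (simulation seeds, correction records, ...).

    Row-level invariants (``0 <= n_dead <= n_total``, ``n_total > 0``,
    finite non-negative concentrations) are enforced at construction.
    Fit-level requirements (at least two distinct positive concentrations)
    are enforced by the fitting routines, since single-dose tables are
    legitimate inputs for diagnostic-dose monitoring.
    """

    def __init__(self, df: pd.DataFrame, meta: Optional[dict] = None):
        df = df.copy()
        missing = [c for c in REQUIRED if c not in df.columns]
        if missing:
            raise ContractError(f"missing required columns: {missing}")
        for c in OPTIONAL:
            if c not in df.columns:
                df[c] = pd.NA
        df = df[COLUMNS].reset_index(drop=True)
        df["concentration_ug_ml"] = df["concentration_ug_ml"].astype(float)
        df["n_total"] = df["n_total"].astype(int)
        df["n_dead"] = df["n_dead"].astype(int)
        self._validate(df)
        self._df = df
        self.meta = dict(meta or {})

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        conc = df["concentration_ug_ml"].to_numpy()
        if not np.all(np.isfinite(conc)):
            raise ContractError("non-finite concentration")
        if (conc < 0).any():
            raise ContractError("negative concentration")
        if (df["n_total"] <= 0).any():
            raise ContractError("n_total must be positive")
        if (df["n_dead"] < 0).any():
            raise ContractError("n_dead must be non-negative")
        bad = df.index[df["n_dead"] > df["n_total"]]
        if len(bad):
            raise ContractError(f"n_dead > n_total at row index {bad[0]}")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[Mapping], meta: Optional[dict] = None
                     ) -> "BioassayTable":
        return cls(pd.DataFrame(list(records)), meta=meta)

    @classmethod
    def from_csv(cls, path) -> "BioassayTable":
        return read_bioassay_csv(path)

    # -- accessors ---------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def subset(self, strain: Optional[str] = None, compound: Optional[str] = None
               ) -> "BioassayTable":
        df = self._df
        if strain is not None:
            df = df[df["strain"] == strain]
        if compound is not None:
            df = df[df["compound"] == compound]
        return BioassayTable(df, meta=self.meta)

    @property
    def treated(self) -> pd.DataFrame:
        return self._df[self._df["concentration_ug_ml"] > 0]

    @property
    def controls(self) -> pd.DataFrame:
        return self._df[self._df["concentration_ug_ml"] == 0]

    def groups(self):
        """Iterate over (strain, compound) -> BioassayTable."""
        for (s, c), g in self._df.groupby(["strain", "compound"], sort=False):
            yield (s, c), BioassayTable(g, meta=self.meta)

    def pooled(self) -> pd.DataFrame:
        """Counts summed over replicates, one row per strain x compound x
        concentration, sorted by concentration within each line."""
        out = (self._df.groupby(
            ["strain", "compound", "concentration_ug_ml"], sort=True)
            [["n_total", "n_dead"]].sum().reset_index())
        return out

    def to_csv(self, path_or_buf=None):
        df = self._df.copy()
        return df.to_csv(path_or_buf, index=False)

    def __repr__(self) -> str:
        lines = self._df.groupby(["strain", "compound"]).ngroups
        return (f"BioassayTable({len(self._df)} rows, {lines} strain/compound "
                f"lines)")


def read_bioassay_csv(path) -> BioassayTable:
    """Read and validate a bioassay CSV.

    The header must contain exactly the declared schema columns (the two
    optional ones may be absent). Values use a decimal point and no
    thousands separators. Errors name the offending data row (1-based,
    counting the header as line 1).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(raw.columns)
    if cols[: len(REQUIRED)] != REQUIRED or any(
            c not in COLUMNS for c in cols):
        raise ParseError(
            f"bad header {cols}; expected {REQUIRED} (+ optional {OPTIONAL})")
    records = []
    for i, row in raw.iterrows():
        line = i + 2  # header is line 1
        conc_s = row["concentration_ug_ml"].strip()
        if "," in conc_s:
            raise ParseError(
                f"row {line}: concentration '{conc_s}' contains a comma — "
                "use a decimal point and no thousands separators")
        try:
            conc = float(conc_s)
            n_total = int(row["n_total"])
            n_dead = int(row["n_dead"])
        except ValueError as e:
            raise ParseError(f"row {line}: {e}") from None
        if conc < 0:
            raise ParseError(f"row {line}: negative concentration {conc}")
        if n_dead > n_total:
            raise ParseError(
                f"row {line}: n_dead={n_dead} exceeds n_total={n_total}")
        if n_total <= 0:
            raise ParseError(f"row {line}: n_total must be positive")
        rec = {
            "strain": row["strain"],
            "compound": row["compound"],
            "concentration_ug_ml": conc,
            "n_total": n_total,
            "n_dead": n_dead,
            "replicate": row.get("replicate", "") or pd.NA,
            "generation": row.get("generation", "") or pd.NA,
        }
        records.append(rec)
    if not records:
        raise ParseError("empty bioassay file")
    return BioassayTable(pd.DataFrame(records))


def abbott_correct(table: BioassayTable, threshold: float = 0.20
                   ) -> BioassayTable:
    """Abbott's control-mortality correction, per (strain, compound) line.

    Treated mortality proportions become ``(obs - c) / (1 - c)`` with ``c``
    the pooled control mortality of the line; corrected counts are rounded
    to the nearest integer and clamped to ``[0, n_total]``. Control rows are
    removed and a correction record is attached to ``meta['abbott']``.

    Raises
    ------
    RejectedAssayError
        If any line's pooled control mortality is at or above ``threshold``
        (default 20%) — the assay is considered failed.

    A table with no control rows passes through unchanged with a warning.
    """
    df = table.df
    if (df["concentration_ug_ml"] == 0).sum() == 0:
        warnings.warn("no control rows; Abbott correction is a no-op")
        out = BioassayTable(df, meta=table.meta)
        out.meta["abbott"] = {"applied": False, "reason": "no control rows"}
        return out
    record = {}
    pieces = []
    for (s, c), g in df.groupby(["strain", "compound"], sort=False):
        ctrl = g[g["concentration_ug_ml"] == 0]
        trt = g[g["concentration_ug_ml"] > 0].copy()
        if len(ctrl) == 0:
            ctrl_mort = 0.0
        else:
            ctrl_mort = ctrl["n_dead"].sum() / ctrl["n_total"].sum()
        if ctrl_mort >= threshold:
            raise RejectedAssayError(
                f"line ({s}, {c}): control mortality {ctrl_mort:.1%} >= "
                f"{threshold:.0%}; assay rejected")
        if ctrl_mort > 0:
            obs = trt["n_dead"] / trt["n_total"]
            corr = ((obs - ctrl_mort) / (1.0 - ctrl_mort)).clip(0.0, 1.0)
            trt["n_dead"] = (
                (corr * trt["n_total"]).round().astype(int)
                .clip(0, trt["n_total"]))
        record[f"{s}/{c}"] = {"control_mortality": float(ctrl_mort),
                              "n_control": int(ctrl["n_total"].sum())}
        pieces.append(trt)
    out = BioassayTable(pd.concat(pieces, ignore_index=True), meta=table.meta)
    out.meta["abbott"] = {"applied": True, "threshold": threshold,
                          "lines": record}
    return out
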