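"""Delimited-text readers and writers for the pipeline tables.

Everything is plain CSV (UTF-8, "." decimal).  Readers validate eagerly and
reject malformed input with an :class:`InputError` listing the offending row
numbers (1-based, excluding the header) instead of coercing silently.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .pk_model import ANALYTES, DoseEvent, Regimen
from .pta import MICDistribution

__all__ = [
    "InputError",
    "CONC_COLUMNS",
    "MATRICES",
    "read_concentrations",
    "write_concentrations",
    "read_doses",
    "regimens_from_doses",
    "read_crrt_settings",
    "read_genotypes",
    "read_subjects",
    "read_mic_table",
    "write_mic_table",
]

CONC_COLUMNS = ["subject_id", "study_day", "time_hr", "analyte", "matrix", "conc_mg_L", "bql"]
MATRICES = ("plasma", "effluent")


class InputError(ValueError):
    """Malformed input table; carries the offending 1-based row numbers."""

    def __init__(self, message: str, rows: Iterable[int] = ()):  # noqa: D107
        self.rows = tuple(rows)
        suffix = f" (rows: {', '.join(map(str, self.rows))})" if self.rows else ""
        super().__init__(message + suffix)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")


def _reject(df: pd.DataFrame, bad: pd.Series, message: str) -> None:
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 1).tolist()
        raise InputError(message, rows=rows)


def read_concentrations(path) -> pd.DataFrame:
    """Read and validate a concentration table.

    Expected header: ``subject_id, study_day, time_hr, analyte, matrix,
    conc_mg_L, bql``.  Analyte and matrix are restricted to their enums,
    times and concentrations must be non-negative and finite, and duplicate
    (subject, analyte, matrix, day, time) records are rejected.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, CONC_COLUMNS, path)
    if df.empty:
        return df[CONC_COLUMNS]
    _reject(df, ~df["analyte"].isin(ANALYTES), f"{path}: unknown analyte")
    _reject(df, ~df["matrix"].isin(MATRICES), f"{path}: unknown matrix")
    for col in ("study_day", "time_hr", "conc_mg_L"):
        vals = pd.to_numeric(df[col], errors="coerce")
        _reject(df, vals.isna() | ~np.isfinite(vals), f"{path}: non-numeric {col}")
        df[col] = vals
    _reject(df, df["time_hr"] < 0, f"{path}: negative time_hr")
    _reject(df, df["conc_mg_L"] < 0, f"{path}: negative conc_mg_L")
    _reject(df, df["study_day"] < 1, f"{path}: study_day must be >= 1")
    df["study_day"] = df["study_day"].astype(int)
    df["bql"] = df["bql"].astype(bool)
    key = ["subject_id", "analyte", "matrix", "study_day", "time_hr"]
    _reject(df, df.duplicated(subset=key, keep=False), f"{path}: duplicate sample records")
    return df[CONC_COLUMNS]


def write_concentrations(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df[CONC_COLUMNS].to_csv(path, index=False)
    return path


def read_doses(path) -> pd.DataFrame:
    """Dose event table: ``subject_id, analyte, amount_mg, start_hr,
    duration_hr[, tau_hr]``."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, ["subject_id", "analyte", "amount_mg", "start_hr", "duration_hr"], path)
    if df.empty:
        return df
    _reject(df, ~df["analyte"].isin(ANALYTES), f"{path}: unknown analyte")
    _reject(df, pd.to_numeric(df["amount_mg"], errors="coerce").isna() | (df["amount_mg"] < 0), f"{path}: bad amount_mg")
    _reject(df, df["duration_hr"] <= 0, f"{path}: non-positive duration_hr")
    _reject(df, df["start_hr"] < 0, f"{path}: negative start_hr")
    return df


def regimens_from_doses(doses: pd.DataFrame) -> dict[tuple[str, str], Regimen]:
    """Group a dose table into per-(subject, analyte) regimens."""
    out: dict[tuple[str, str], Regimen] = {}
    for (sid, analyte), grp in doses.groupby(["subject_id", "analyte"], sort=True):
        tau = None
        if "tau_hr" in grp.columns and grp["tau_hr"].notna().any():
            tau = float(grp["tau_hr"].dropna().iloc[0])
        events = tuple(
            DoseEvent(analyte, float(r.amount_mg), float(r.start_hr), float(r.duration_hr))
            for r in grp.itertuples()
        )
        out[(str(sid), str(analyte))] = Regimen(events=events, tau=tau)
    return out


def read_crrt_settings(path) -> pd.DataFrame:
    """CRRT settings table: ``subject_id, blood_flow_ml_min, predilution_ml_hr,
    net_uf_ml_hr, hematocrit``."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(
        df, ["subject_id", "blood_flow_ml_min", "predilution_ml_hr", "net_uf_ml_hr", "hematocrit"], path
    )
    if df.empty:
        return df
    _reject(df, df["blood_flow_ml_min"] <= 0, f"{path}: non-positive blood flow")
    _reject(df, (df["predilution_ml_hr"] < 0) | (df["net_uf_ml_hr"] < 0), f"{path}: negative flow")
    _reject(df, (df["hematocrit"] < 0) | (df["hematocrit"] >= 1), f"{path}: hematocrit outside [0, 1)")
    return df


def read_genotypes(path) -> pd.DataFrame:
    """Genotype table: ``subject_id, allele1, allele2`` (star alleles)."""
    from .pgx import ALLELES

    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["subject_id", "allele1", "allele2"], path)
    if df.empty:
        return df
    for col in ("allele1", "allele2"):
        _reject(df, ~df[col].isin(ALLELES), f"{path}: unknown CYP2C19 allele in {col}")
    return df


def read_subjects(path) -> pd.DataFrame:
    """Demographics table: ``subject_id, weight_kg``."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, ["subject_id", "weight_kg"], path)
    if not df.empty:
        _reject(df, df["weight_kg"] <= 0, f"{path}: non-positive weight")
    return df


def read_mic_table(path) -> list[MICDistribution]:
    """MIC CSV (``organism, source, mic_mg_L, n_isolates``) to distributions."""
    df = pd.read_csv(path)
    _require_columns(df, ["organism", "source", "mic_mg_L", "n_isolates"], path)
    out = []
    for (org, src), grp in df.groupby(["organism", "source"], sort=True):
        out.append(
            MICDistribution.from_mapping(
                str(org), str(src), dict(zip(grp["mic_mg_L"], grp["n_isolates"]))
            )
        )
    return out


def write_mic_table(dists: list[MICDistribution], path) -> Path:
    rows = [
        {"organism": d.organism, "source": d.source, "mic_mg_L": m, "n_isolates": c}
        for d in dists
        for m, c in zip(d.mics, d.counts)
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
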