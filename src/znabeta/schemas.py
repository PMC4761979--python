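"""CSV dataset schemas, validation, and conversion to analysis objects.

All datasets are comma-separated UTF-8 with a mandatory header row and '.'
decimal separator; units are encoded in column names (``_mM``, ``_ppm``,
``_s``, ``_uL``, ``_uJ``).  ``validate_dataset`` returns the complete list
of violations, never just the first.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .itc import ITCExperiment
from .jobplot import JobSeries
from .magtransfer import ExchangeDataset
from .titration import TitrationPoint, TitrationSeries

__all__ = [
    "SCHEMAS",
    "SchemaViolation",
    "validate_dataset",
    "file_sha256",
    "titration_to_frame",
    "frame_to_titration",
    "job_to_frame",
    "frame_to_job",
    "mt_to_frame",
    "frame_to_mt",
    "itc_to_frame",
    "frame_to_itc",
]

SCHEMAS: dict[str, dict] = {
    "titration": {
        "columns": {
            "point_index": int,
            "zn_equivalents": float,
            "volume_uL": float,
            "reporter_id": str,
            "nucleus": str,
            "shift_ppm": float,
        },
    },
    "job": {
        "columns": {
            "mole_fraction_zn": float,
            "reporter_id": str,
            "delta_delta_ppm": float,
            "peptide_total_mM": float,
        },
    },
    "mt": {
        "columns": {
            "delay_s": float,
            "intensity_monomer": float,
            "intensity_dimer": float,
        },
    },
    "itc": {
        "columns": {
            "injection_index": int,
            "heat_uJ": float,
        },
    },
}


@dataclass(frozen=True)
class SchemaViolation:
    schema_id: str
    kind: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.schema_id}/{self.kind}] {self.detail}"


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _check_numeric(df: pd.DataFrame, col: str, schema_id: str,
                   out: list[SchemaViolation]) -> None:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[coerced.isna() & df[col].notna()]
    for i in bad:
        out.append(SchemaViolation(
            schema_id, "non-numeric",
            f"column {col!r} row {i}: {df.at[i, col]!r}"))
    if df[col].isna().any():
        out.append(SchemaViolation(
            schema_id, "missing-value", f"column {col!r} has empty cells"))


def validate_dataset(
    path: str | Path, schema_id: str
) -> tuple[pd.DataFrame | None, list[SchemaViolation]]:
    """Read and validate a CSV dataset against a named schema.

    Returns the parsed frame (or None if unreadable) together with the
    complete list of violations; an empty list means the dataset is valid.
    """
    if schema_id not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_id!r}; "
                       f"known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    violations: list[SchemaViolation] = []
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        return None, [SchemaViolation(schema_id, "unreadable", str(exc))]

    spec = SCHEMAS[schema_id]["columns"]
    missing = [c for c in spec if c not in df.columns]
    for c in missing:
        violations.append(SchemaViolation(schema_id, "missing-column", c))
    for c, typ in spec.items():
        if c in df.columns and typ in (int, float):
            _check_numeric(df, c, schema_id, violations)
    if violations:
        return df, violations

    if schema_id == "mt":
        d = df["delay_s"].to_numpy(dtype=float)
        if np.any(d < 0):
            violations.append(SchemaViolation("mt", "ordering",
                                              "negative delays"))
        if np.any(np.diff(d) <= 0):
            violations.append(SchemaViolation(
                "mt", "ordering", "delays must be strictly increasing"))
    elif schema_id == "titration":
        for rid, grp in df.groupby("reporter_id"):
            eq = grp.sort_values("point_index")["zn_equivalents"].to_numpy()
            if eq.size and eq[0] != 0.0:
                violations.append(SchemaViolation(
                    "titration", "ordering",
                    f"reporter {rid!r}: first point must have zero zinc"))
            if np.any(np.diff(eq) < 0):
                violations.append(SchemaViolation(
                    "titration", "ordering",
                    f"reporter {rid!r}: zinc equivalents decrease"))
    elif schema_id == "job":
        for rid, grp in df.groupby("reporter_id"):
            x = grp["mole_fraction_zn"].to_numpy(dtype=float)
            if np.any((x < 0) | (x > 1)):
                violations.append(SchemaViolation(
                    "job", "range",
                    f"reporter {rid!r}: mole fractions outside [0, 1]"))
            if np.any(np.diff(x) <= 0):
                violations.append(SchemaViolation(
                    "job", "ordering",
                    f"reporter {rid!r}: mole fractions not increasing"))
    elif schema_id == "itc":
        idx = df["injection_index"].to_numpy()
        if np.any(np.diff(idx) != 1) or (idx.size and idx[0] != 1):
            violations.append(SchemaViolation(
                "itc", "ordering", "injection_index must run 1..n"))
    return df, violations


# ---------------------------------------------------------------- titration

def titration_to_frame(series: TitrationSeries) -> pd.DataFrame:
    rows = []
    for i, pt in enumerate(series.points):
        pep = pt.peptide_total
        eq = pt.zn_total / pep if pep > 0 else 0.0
        for rid, shift in pt.shifts.items():
            rows.append({
                "point_index": i,
                "zn_equivalents": eq,
                "volume_uL": pt.volume_uL,
                "reporter_id": rid,
                "nucleus": series.reporters.get(rid, "1H"),
                "shift_ppm": shift,
            })
    return pd.DataFrame(rows)


def frame_to_titration(
    df: pd.DataFrame,
    peptide_mM: float,
    dilution_correction: bool = True,
) -> TitrationSeries:
    """Rebuild a TitrationSeries from the long-format CSV frame.

    ``peptide_mM`` is the peptide concentration at the first (zinc-free)
    point.  With ``dilution_correction`` the per-point peptide total is
    scaled by initial_volume/volume; without it the starting concentration
    is used throughout (for quantifying the bias the correction removes).
    """
    P0 = peptide_mM * 1e-3
    v0 = float(df.loc[df["point_index"] == df["point_index"].min(),
                      "volume_uL"].iloc[0])
    reporters = (df.drop_duplicates("reporter_id")
                   .set_index("reporter_id")["nucleus"].to_dict())
    pts = []
    for _, grp in df.groupby("point_index", sort=True):
        vol = float(grp["volume_uL"].iloc[0])
        eq = float(grp["zn_equivalents"].iloc[0])
        pep = P0 * v0 / vol if dilution_correction else P0
        shifts = dict(zip(grp["reporter_id"], grp["shift_ppm"].astype(float)))
        pts.append(TitrationPoint(eq * pep, vol, pep, shifts))
    return TitrationSeries(tuple(pts), reporters)


# ---------------------------------------------------------------------- job

def job_to_frame(series: JobSeries, reporter_id: str = "r1") -> pd.DataFrame:
    return pd.DataFrame({
        "mole_fraction_zn": series.mole_fraction_zn,
        "reporter_id": reporter_id,
        "delta_delta_ppm": series.delta_delta,
        "peptide_total_mM": series.peptide_total * 1e3,
    })


def frame_to_job(df: pd.DataFrame, reporter_id: str | None = None) -> JobSeries:
    if reporter_id is not None:
        df = df[df["reporter_id"] == reporter_id]
    x = df["mole_fraction_zn"].to_numpy(dtype=float)
    pep = df["peptide_total_mM"].to_numpy(dtype=float) * 1e-3
    total = float(np.median(pep / (1.0 - x)))
    return JobSeries(total, x, df["delta_delta_ppm"].to_numpy(dtype=float), pep)


# ----------------------------------------------------------------------- mt

def mt_to_frame(ds: ExchangeDataset) -> pd.DataFrame:
    return pd.DataFrame({
        "delay_s": ds.delays,
        "intensity_monomer": ds.I_mono,
        "intensity_dimer": ds.I_dimer,
    })


def frame_to_mt(df: pd.DataFrame, inverted_site: str = "mono") -> ExchangeDataset:
    return ExchangeDataset(
        df["delay_s"].to_numpy(dtype=float),
        df["intensity_monomer"].to_numpy(dtype=float),
        df["intensity_dimer"].to_numpy(dtype=float),
        inverted_site,
    )


# ---------------------------------------------------------------------- itc

def itc_to_frame(exp: ITCExperiment) -> pd.DataFrame:
    return pd.DataFrame({
        "injection_index": np.arange(1, exp.n_injections + 1),
        "heat_uJ": exp.heats * 1e6,
    })


def frame_to_itc(
    df: pd.DataFrame,
    syringe_zn_mM: float,
    cell_peptide_mM: float,
    cell_volume: float = 2.0e-4,
    injection_volume: float = 2.0e-6,
) -> ITCExperiment:
    return ITCExperiment(
        syringe_zn=syringe_zn_mM * 1e-3,
        cell_peptide=cell_peptide_mM * 1e-3,
        heats=df.sort_values("injection_index")["heat_uJ"]
                .to_numpy(dtype=float) * 1e-6,
        cell_volume=cell_volume,
        injection_volume=injection_volume,
    )
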