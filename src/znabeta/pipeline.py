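"""Analysis orchestration: run declared analyses over datasets, emit reports.

A pipeline config is a JSON-compatible dict::

    {
      "seed": 42,
      "analyses": [
        {"kind": "titration", "path": "tit.csv",
         "params": {"peptide_mM": 1.0}},
        {"kind": "mt", "path": "mt.csv", "params": {}},
        ...
      ]
    }

Each stage validates its dataset, runs the analysis, and contributes an
:class:`AnalysisReport` whose numbers are traceable to the input checksum
and parameter set.  Stage failures are isolated: one bad dataset does not
abort the others.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .equilibria import (SpeciesSystem, dimer_chain_fraction,
                         solve_equilibrium)
from .itc import fit_itc
from .jobplot import job_product, locate_maximum, stoichiometry_from_xmax
from .magtransfer import fit_exchange
from .schemas import (file_sha256, frame_to_itc, frame_to_job, frame_to_mt,
                      frame_to_titration, validate_dataset)
from .titration import fit_binding, scatchard_transform

__all__ = ["AnalysisReport", "run_pipeline", "run_equilibrium_grid"]

log = logging.getLogger("znabeta")


@dataclass
class AnalysisReport:
    """One analysis stage: provenance, fitted parameters, diagnostics."""

    kind: str
    input_path: str | None
    input_sha256: str | None
    parameters: dict
    results: dict
    diagnostics: dict = field(default_factory=dict)
    version: str = __version__
    seed: int | None = None
    ok: bool = True
    error: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _run_titration(path: Path, params: dict) -> tuple[dict, dict]:
    df, violations = validate_dataset(path, "titration")
    if violations:
        raise ValueError("; ".join(map(str, violations)))
    series = frame_to_titration(
        df, peptide_mM=params["peptide_mM"],
        dilution_correction=params.get("dilution_correction", True))
    fit = fit_binding(series, reporters=params.get("reporters"),
                      noise_floor=params.get("noise_floor", 0.005))
    scat = scatchard_transform(series, fit)
    return (
        {"Ka_per_M": fit.Ka, "Ka_stderr": fit.Ka_stderr,
         "delta_free_ppm": fit.delta_free, "delta_bound_ppm": fit.delta_bound},
        {"residual_norm": fit.residual_norm,
         "scatchard_r_squared": scat.r_squared,
         "scatchard_slope": scat.slope,
         "reporters_used": list(fit.reporters)},
    )


def _run_job(path: Path, params: dict) -> tuple[dict, dict]:
    df, violations = validate_dataset(path, "job")
    if violations:
        raise ValueError("; ".join(map(str, violations)))
    results, diags = {}, {}
    for rid in df["reporter_id"].unique():
        series = frame_to_job(df, reporter_id=rid)
        prod = job_product(series)
        jm = locate_maximum(series.mole_fraction_zn, prod)
        snapped, real = stoichiometry_from_xmax(
            jm.x_max, snap_tolerance=params.get("snap_tolerance", 0.05))
        results[rid] = {
            "x_max": jm.x_max, "x_max_stderr": jm.x_max_stderr,
            "stoichiometry_zn_per_peptide": float(real),
            "stoichiometry_label": str(snapped),
        }
        diags[rid] = {"n_points": int(series.mole_fraction_zn.size)}
    return results, diags


def _run_mt(path: Path, params: dict) -> tuple[dict, dict]:
    df, violations = validate_dataset(path, "mt")
    if violations:
        raise ValueError("; ".join(map(str, violations)))
    ds = frame_to_mt(df, inverted_site=params.get("inverted_site", "mono"))
    res = fit_exchange(ds, shared_R1=params.get("shared_R1", True),
                       fixed=params.get("fixed"))
    m = res.model
    return (
        {"k_md_per_s": m.k_md, "k_md_stderr": res.k_md_stderr,
         "k_dm_per_s": m.k_dm, "k_dm_stderr": res.k_dm_stderr,
         "R1_m_per_s": m.R1_m, "R1_d_per_s": m.R1_d,
         "dimer_fraction": m.k_md / (m.k_md + m.k_dm)},
        {"residual_norm": res.residual_norm,
         "covar_condition": res.covar_condition,
         "ill_conditioned": res.ill_conditioned},
    )


def _run_itc(path: Path, params: dict) -> tuple[dict, dict]:
    df, violations = validate_dataset(path, "itc")
    if violations:
        raise ValueError("; ".join(map(str, violations)))
    exp = frame_to_itc(
        df,
        syringe_zn_mM=params["syringe_zn_mM"],
        cell_peptide_mM=params["cell_peptide_mM"],
        cell_volume=params.get("cell_volume", 2.0e-4),
        injection_volume=params.get("injection_volume", 2.0e-6),
    )
    fit = fit_itc(exp)
    return (
        {"Ka_per_M": fit.Ka, "Ka_stderr": fit.Ka_stderr,
         "dH_J_per_mol": fit.dH, "N": fit.N, "baseline_J": fit.baseline},
        {"c_value": fit.c_value, "low_confidence": fit.low_confidence,
         "residual_norm": fit.residual_norm},
    )


_RUNNERS = {
    "titration": _run_titration,
    "job": _run_job,
    "mt": _run_mt,
    "itc": _run_itc,
}


def run_equilibrium_grid(
    Ka_mono: float,
    Kdim: float,
    P_grid_mM,
    zn_equivalents: float = 0.5,
):
    """Species concentrations and dimer fraction over a peptide grid.

    Returns a list of per-point dicts matching the equilibrium CSV columns.
    """
    rows = []
    for p_mM in np.asarray(P_grid_mM, dtype=float):
        Pt = p_mM * 1e-3
        Zt = zn_equivalents * Pt
        st = solve_equilibrium(SpeciesSystem(Ka_mono, Kdim, Pt, Zt))
        rows.append({
            "P_total_mM": p_mM, "Zn_total_mM": Zt * 1e3,
            "P": st.conc_P, "Zn": st.conc_Zn,
            "PZn": st.conc_PZn, "P2Zn": st.conc_P2Zn,
            "dimer_chain_fraction": dimer_chain_fraction(st),
            "residual_P": st.residual_P, "residual_Zn": st.residual_Zn,
        })
    return rows


def run_pipeline(config: dict, base_dir: str | Path = ".") -> list[AnalysisReport]:
    """Execute every analysis declared in the config; never raises per-stage.

    Returns one report per declared analysis, failed stages included with
    ``ok=False`` and the error message.  An empty analysis list yields an
    empty report list with a warning.
    """
    base = Path(base_dir)
    analyses = config.get("analyses", [])
    seed = config.get("seed")
    if not analyses:
        log.warning("pipeline config declares no analyses; nothing to do")
        return []
    reports = []
    for spec in analyses:
        kind = spec.get("kind")
        path = base / spec["path"]
        params = spec.get("params", {})
        t0 = time.monotonic()
        checksum = file_sha256(path) if path.exists() else None
        try:
            if kind not in _RUNNERS:
                raise KeyError(f"unknown analysis kind {kind!r}")
            results, diags = _RUNNERS[kind](path, params)
            rep = AnalysisReport(kind, str(path), checksum, params,
                                 results, diags, seed=seed)
        except Exception as exc:
            rep = AnalysisReport(kind, str(path), checksum, params, {},
                                 seed=seed, ok=False, error=str(exc))
        log.info("stage=%s input=%s sha256=%s elapsed=%.3fs ok=%s",
                 kind, path, (checksum or "")[:12],
                 time.monotonic() - t0, rep.ok)
        reports.append(rep)
    return reports
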