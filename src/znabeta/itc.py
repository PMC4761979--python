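"""Single-site ITC: forward Wiseman isotherm and nonlinear fit.

Heat-per-injection model for a titration of zinc into a peptide solution in
an overflow (perfusion) calorimeter cell: each injection of volume v into
the cell of volume V0 displaces an equal volume of mixed solution, so the
retained fraction per injection is (1 - v/V0).  After each injection the
1:1 binding quadratic (with N binding sites per peptide) gives the bound
concentration, and the measured heat is the enthalpy of the newly formed
complex plus a constant baseline (heat of dilution):

    q_i = V0 * dH * ([B]_i - [B]_{i-1} * (1 - v/V0)) + baseline

The isotherm shape is governed by the Wiseman c-value c = Ka * N * [P]cell;
Ka is well determined roughly for c in [1, 1000].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

__all__ = ["ITCExperiment", "ITCFit", "injection_heats", "fit_itc"]


@dataclass(frozen=True)
class ITCExperiment:
    """Calorimeter geometry, concentrations and observed heats.

    Defaults reflect a MicroCal iTC200-class instrument: a 0.2 mL cell
    titrated with 2 uL injections.  ``heats`` are per-injection heats in
    joules; ``syringe_zn`` and ``cell_peptide`` are molar.
    """

    syringe_zn: float
    cell_peptide: float
    heats: np.ndarray
    cell_volume: float = 2.0e-4
    injection_volume: float = 2.0e-6
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.cell_volume <= 0 or self.injection_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.syringe_zn < 0 or self.cell_peptide <= 0:
            raise ValueError("concentrations invalid")
        h = np.asarray(self.heats, dtype=float)
        object.__setattr__(self, "heats", h)

    @property
    def n_injections(self) -> int:
        return int(self.heats.size)


@dataclass(frozen=True)
class ITCFit:
    """Fitted single-site parameters with uncertainties and diagnostics."""

    Ka: float
    dH: float
    N: float
    baseline: float
    Ka_stderr: float | None
    dH_stderr: float | None
    N_stderr: float | None
    c_value: float
    low_confidence: bool
    residual_norm: float
    covar: np.ndarray | None = field(repr=False, default=None)


def _bound_conc(Ka: float, sites: np.ndarray, zn: np.ndarray) -> np.ndarray:
    """[bound] from the 1:1 quadratic with total site concentration."""
    if Ka == 0:
        return np.zeros_like(sites)
    a = sites + zn + 1.0 / Ka
    return 0.5 * (a - np.sqrt(np.maximum(a * a - 4.0 * sites * zn, 0.0)))


def cell_concentrations(
    experiment: ITCExperiment, n: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Dilution-corrected (peptide, zinc) totals in the cell after each injection.

    Overflow convention: per injection the cell retains the fraction
    (1 - v/V0) of what it held, and receives the full injected titrant
    (treated as instantly mixed).  With d = 1 - v/V0,
    after i injections: peptide = P0 * d^i, zinc = Zn_syr * (1 - d^i).
    """
    n = experiment.n_injections if n is None else n
    d = 1.0 - experiment.injection_volume / experiment.cell_volume
    i = np.arange(1, n + 1)
    pep = experiment.cell_peptide * d**i
    zn = experiment.syringe_zn * (1.0 - d**i)
    return pep, zn


def injection_heats(
    Ka: float,
    dH: float,
    N: float,
    experiment: ITCExperiment,
    baseline: float = 0.0,
    n: int | None = None,
) -> np.ndarray:
    """Forward-model per-injection heats (J) for a single-site isotherm.

    ``dH`` is the molar binding enthalpy (J/mol); ``N`` the number of zinc
    sites per peptide; ``baseline`` a constant heat of dilution per
    injection.
    """
    n = experiment.n_injections if n is None else n
    d = 1.0 - experiment.injection_volume / experiment.cell_volume
    pep, zn = cell_concentrations(experiment, n)
    bound = _bound_conc(Ka, N * pep, zn)
    prev = np.concatenate([[0.0], bound[:-1]])
    # heat from complex newly formed in the cell; the expelled volume carries
    # away a share of the previous complex without generating heat
    dq = experiment.cell_volume * dH * (bound - prev * d)
    return dq + baseline


def fit_itc(
    experiment: ITCExperiment,
    c_bounds: tuple[float, float] = (1.0, 1000.0),
) -> ITCFit:
    """Nonlinear least squares of (Ka, dH, N, baseline) to observed heats.

    Requires at least 10 injections spanning sub- to super-stoichiometric
    molar ratio.  Reports the Wiseman c-value Ka*N*[P]cell; a fit with c
    outside ``c_bounds`` is flagged low-confidence because the isotherm
    shape then under-determines Ka.
    """
    if experiment.n_injections < 10:
        raise ValueError("need at least 10 injections")
    obs = experiment.heats
    scale = float(np.max(np.abs(obs)))
    if scale == 0:
        raise ValueError("all heats are zero")

    # Rough initializers: total heat ~ V0*dH*[P] at saturation; equivalence
    # near where |heat| has dropped to half its initial magnitude.
    dh0 = float(np.sum(obs) / (experiment.cell_volume * experiment.cell_peptide))
    dh0 = dh0 if abs(dh0) > 0 else (-1e4 if obs[0] < 0 else 1e4)

    params = Parameters()
    params.add("logKa", value=4.0, min=0.0, max=9.0)
    params.add("dH", value=dh0, min=-1e7, max=1e7)
    params.add("N", value=1.0, min=0.05, max=10.0)
    params.add("baseline", value=float(obs[-1]), min=-10 * scale, max=10 * scale)

    def residual(p):
        sim = injection_heats(10.0 ** p["logKa"].value, p["dH"].value,
                              p["N"].value, experiment, p["baseline"].value)
        return sim - obs

    out = minimize(residual, params, method="leastsq")
    ka = float(10.0 ** out.params["logKa"].value)
    lg_err = out.params["logKa"].stderr
    ka_err = ka * np.log(10.0) * lg_err if lg_err is not None else None
    n_fit = float(out.params["N"].value)
    c = ka * n_fit * experiment.cell_peptide
    return ITCFit(
        Ka=ka,
        dH=float(out.params["dH"].value),
        N=n_fit,
        baseline=float(out.params["baseline"].value),
        Ka_stderr=ka_err,
        dH_stderr=out.params["dH"].stderr,
        N_stderr=out.params["N"].stderr,
        c_value=float(c),
        low_confidence=not (c_bounds[0] <= c <= c_bounds[1]),
        residual_norm=float(np.sqrt(np.sum(out.residual**2))),
        covar=getattr(out, "covar", None),
    )
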