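"""Coupled zinc-binding / zinc-bridged dimerization equilibria.

The model is the two-step scheme used for the amyloid-beta metal-binding
domain: a peptide chain P binds Zn2+ to form the monomeric complex PZn
(association constant ``Ka_mono``), and a second chain adds to the complex
to form the zinc-bridged dimer P2Zn (association constant ``Kdim``)::

    P + Zn  <=> PZn        [PZn]  = Ka_mono * [P] * [Zn]
    PZn + P <=> P2Zn       [P2Zn] = Kdim    * [PZn] * [P]

Both chains of the dimer share a single bridging zinc ion, so the dimer
carries two chains and one zinc.  All concentrations are molar; association
constants are per-molar.

The module solves the two mass balances for free [P] and free [Zn], converts
slow-exchange NMR rate constants into an equilibrium dimer fraction through
detailed balance, calibrates ``Kdim`` against that fraction, and predicts
how the dimer fraction grows with total peptide concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpeciesSystem",
    "EquilibriumState",
    "ExchangeRates",
    "EquilibriumError",
    "InfeasibleTargetError",
    "solve_equilibrium",
    "dimer_chain_fraction",
    "fraction_from_rates",
    "calibrate_kdim",
    "predict_dimer_curve",
]


class EquilibriumError(RuntimeError):
    """Mass-balance solver failed to converge.

    Carries the last residuals so the caller can judge how badly.
    """

    def __init__(self, message: str, residual_P: float, residual_Zn: float):
        super().__init__(message)
        self.residual_P = residual_P
        self.residual_Zn = residual_Zn


class InfeasibleTargetError(ValueError):
    """Requested dimer fraction cannot be reached at the given totals."""


@dataclass(frozen=True)
class SpeciesSystem:
    """Equilibrium constants and totals defining the P/Zn/PZn/P2Zn scheme.

    Parameters
    ----------
    Ka_mono : float
        Association constant of P + Zn <=> PZn, M^-1.
    Kdim : float
        Association constant of PZn + P <=> P2Zn, M^-1.
    P_total : float
        Total peptide chain concentration, M (chains, counting each dimer
        subunit separately).
    Zn_total : float
        Total zinc concentration, M.
    """

    Ka_mono: float
    Kdim: float
    P_total: float
    Zn_total: float

    def __post_init__(self) -> None:
        if self.Ka_mono < 0 or self.Kdim < 0:
            raise ValueError("association constants must be non-negative")
        if self.P_total <= 0:
            raise ValueError("P_total must be positive")
        if self.Zn_total < 0:
            raise ValueError("Zn_total must be non-negative")


@dataclass(frozen=True)
class EquilibriumState:
    """Converged species concentrations (molar) and mass-balance residuals."""

    conc_P: float
    conc_Zn: float
    conc_PZn: float
    conc_P2Zn: float
    residual_P: float
    residual_Zn: float
    system: SpeciesSystem = field(repr=False)


@dataclass(frozen=True)
class ExchangeRates:
    """Effective monomer<->dimer exchange rates and their conditions.

    ``k_md`` is the effective monomer-to-dimer rate (pseudo-first-order at
    the concentration where it was measured) and ``k_dm`` the dimer-to-monomer
    rate, both s^-1.  ``P_total``/``Zn_total`` record the conditions of the
    measurement (molar); they are metadata, not used in the arithmetic.
    """

    k_md: float
    k_dm: float
    P_total: float | None = None
    Zn_total: float | None = None

    def __post_init__(self) -> None:
        if self.k_md <= 0 or self.k_dm <= 0:
            raise ValueError("exchange rates must be positive")


def _residuals(logP: float, logZn: float, sys: SpeciesSystem) -> tuple[float, float]:
    P = np.exp(logP)
    Zn = np.exp(logZn)
    PZn = sys.Ka_mono * P * Zn
    P2Zn = sys.Kdim * PZn * P
    rP = P + PZn + 2.0 * P2Zn - sys.P_total
    rZn = Zn + PZn + P2Zn - sys.Zn_total
    return rP, rZn


def solve_equilibrium(
    system: SpeciesSystem,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> EquilibriumState:
    """Solve the two mass balances for the free-species concentrations.

    Works in log-concentration variables (free P and free Zn stay positive
    by construction) with a damped Newton iteration.  Deterministic; the
    starting point is half of each total.

    Parameters
    ----------
    system : SpeciesSystem
    tol : float
        Relative convergence tolerance: both residuals must fall below
        ``tol * max(P_total, Zn_total)``.
    max_iter : int
        Iteration cap before raising :class:`EquilibriumError`.
    """
    Ka, Kd = system.Ka_mono, system.Kdim
    Pt, Zt = system.P_total, system.Zn_total
    scale = max(Pt, Zt)

    # Degenerate cases have closed forms; take them and skip the iteration.
    if Zt == 0.0 or Ka == 0.0:
        return EquilibriumState(Pt, Zt, 0.0, 0.0, 0.0, 0.0, system)

    lP, lZ = np.log(Pt / 2.0), np.log(Zt / 2.0)
    rP, rZ = _residuals(lP, lZ, system)
    norm = max(abs(rP), abs(rZ))

    for _ in range(max_iter):
        if norm <= tol * scale:
            break
        P, Zn = np.exp(lP), np.exp(lZ)
        PZn = Ka * P * Zn
        P2Zn = Kd * PZn * P
        # Jacobian of the residuals w.r.t. (log P, log Zn)
        j11 = P + PZn + 4.0 * P2Zn
        j12 = PZn + 2.0 * P2Zn
        j21 = PZn + 2.0 * P2Zn
        j22 = Zn + PZn + P2Zn
        det = j11 * j22 - j12 * j21
        if det == 0.0 or not np.isfinite(det):
            raise EquilibriumError("singular Jacobian", rP, rZ)
        dP = -(j22 * rP - j12 * rZ) / det
        dZ = -(-j21 * rP + j11 * rZ) / det
        # Damp: halve the step until the residual norm decreases.
        step = 1.0
        while True:
            nP, nZ = _residuals(lP + step * dP, lZ + step * dZ, system)
            nnorm = max(abs(nP), abs(nZ))
            if nnorm < norm or step < 1e-8:
                break
            step *= 0.5
        lP += step * dP
        lZ += step * dZ
        rP, rZ, norm = nP, nZ, nnorm
    else:
        raise EquilibriumError(
            f"no convergence after {max_iter} iterations", rP, rZ
        )

    P, Zn = float(np.exp(lP)), float(np.exp(lZ))
    PZn = Ka * P * Zn
    P2Zn = Kd * PZn * P
    return EquilibriumState(P, Zn, PZn, P2Zn, float(rP), float(rZ), system)


def dimer_chain_fraction(state: EquilibriumState, P_total: float | None = None) -> float:
    """Fraction of peptide chains residing in dimers, ``2*[P2Zn]/P_total``.

    Defined on chains because both chains of the dimer contribute to the
    dimer-specific NMR resonances, so intensity-based percentages count
    chains, not dimer particles.
    """
    Pt = state.system.P_total if P_total is None else P_total
    return 2.0 * state.conc_P2Zn / Pt


def fraction_from_rates(rates: ExchangeRates) -> float:
    """Equilibrium dimer chain fraction implied by two-site exchange rates.

    Detailed balance for slow monomer<->dimer exchange requires
    ``k_md * f_mono = k_dm * f_dimer``, hence
    ``f_dimer = k_md / (k_md + k_dm)``.
    """
    return rates.k_md / (rates.k_md + rates.k_dm)


def calibrate_kdim(
    Ka_mono: float,
    P_total: float,
    Zn_total: float,
    target_fraction: float,
    tol: float = 1e-10,
) -> float:
    """Find the ``Kdim`` that reproduces a measured dimer chain fraction.

    The dimer fraction is strictly increasing in ``Kdim`` at fixed totals,
    so this is a 1-D monotone root find (bisection on log10 Kdim).

    Raises
    ------
    InfeasibleTargetError
        If the target fraction exceeds what even an arbitrarily strong
        dimerization constant could produce at these totals (zinc-limited).
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie in (0, 1)")
    if Ka_mono <= 0:
        raise ValueError("Ka_mono must be positive")

    def frac(kdim: float) -> float:
        st = solve_equilibrium(SpeciesSystem(Ka_mono, kdim, P_total, Zn_total))
        return dimer_chain_fraction(st)

    lo, hi = -8.0, 16.0
    if frac(10.0**hi) < target_fraction:
        raise InfeasibleTargetError(
            f"target fraction {target_fraction} unattainable at "
            f"P_total={P_total}, Zn_total={Zn_total}"
        )
    if frac(10.0**lo) > target_fraction:  # pragma: no cover - would need huge Ka
        raise InfeasibleTargetError("target fraction below the Kdim=0 limit")

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(10.0**mid) < target_fraction:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 10.0 ** (0.5 * (lo + hi))


def predict_dimer_curve(
    Ka_mono: float,
    Kdim: float,
    P_grid,
    zn_equivalents: float = 0.5,
) -> np.ndarray:
    """Dimer chain fraction over a grid of total peptide concentrations.

    ``zn_equivalents`` sets Zn_total = zn_equivalents * P_total at every grid
    point (the titration convention: zinc tracks peptide).  The returned
    fractions are monotone non-decreasing along an increasing grid.
    """
    P_grid = np.asarray(P_grid, dtype=float)
    if np.any(P_grid <= 0):
        raise ValueError("P_grid must be positive")
    out = np.empty_like(P_grid)
    for i, Pt in enumerate(P_grid.ravel()):
        st = solve_equilibrium(
            SpeciesSystem(Ka_mono, Kdim, Pt, zn_equivalents * Pt)
        )
        out.ravel()[i] = dimer_chain_fraction(st)
    return out
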