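"""Method of continuous variations (Job plot) for binding stoichiometry.

A Job series holds samples at a fixed total concentration C with the zinc
mole fraction x swept across (0, 1): Zn_total = x*C, peptide_total =
(1-x)*C.  The product of the shift change and the peptide concentration,
delta_delta * [P]0, is proportional to the complex concentration, so its
maximum along x locates the binding stoichiometry: a maximum at x = 0.5
means 1:1, at x = 1/3 means 1 Zn : 2 peptide, etc.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "JobSeries",
    "JobMaximum",
    "NoInteriorMaximumError",
    "job_product",
    "locate_maximum",
    "stoichiometry_from_xmax",
]

SNAP_TOLERANCE = 0.05  # on x_max, for reporting small-integer ratios


class NoInteriorMaximumError(ValueError):
    """The empirical maximum sits on the boundary of the sampled range."""


@dataclass(frozen=True)
class JobSeries:
    """Continuous-variation series at fixed total concentration.

    ``mole_fraction_zn`` strictly increasing in (0, 1); ``delta_delta`` the
    shift change (ppm) of one reporter at each point; ``peptide_total`` the
    peptide concentration at each point, which must satisfy
    peptide_total = (1 - x) * total_concentration.
    """

    total_concentration: float
    mole_fraction_zn: np.ndarray
    delta_delta: np.ndarray
    peptide_total: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.mole_fraction_zn, dtype=float)
        dd = np.asarray(self.delta_delta, dtype=float)
        pt = np.asarray(self.peptide_total, dtype=float)
        if not (x.shape == dd.shape == pt.shape):
            raise ValueError("mole fractions, shifts and totals must align")
        if x.size == 0:
            raise ValueError("series is empty")
        if np.any(np.diff(x) <= 0):
            raise ValueError("mole fractions must be strictly increasing")
        if np.any((x < 0) | (x > 1)):
            raise ValueError("mole fractions must lie in [0, 1]")
        if not np.allclose(pt + x * self.total_concentration,
                           self.total_concentration, rtol=1e-6):
            raise ValueError("peptide + zinc must equal the fixed total")
        object.__setattr__(self, "mole_fraction_zn", x)
        object.__setattr__(self, "delta_delta", dd)
        object.__setattr__(self, "peptide_total", pt)


@dataclass(frozen=True)
class JobMaximum:
    x_max: float
    x_max_stderr: float
    n_points_used: int


def job_product(series: JobSeries) -> np.ndarray:
    """Per-point product delta_delta * [P]0 (ppm * M)."""
    return series.delta_delta * series.peptide_total


def locate_maximum(
    x: np.ndarray,
    products: np.ndarray,
    n_local: int = 5,
) -> JobMaximum:
    """Vertex of a local quadratic fit around the empirical maximum.

    Fits a parabola to the ``n_local`` points nearest the empirical maximum
    (ties broken toward smaller x) and returns its vertex; the uncertainty
    is propagated from the covariance of the quadratic coefficients.  A
    quadratic is robust to the flattening of Job curves under weak binding.

    Raises
    ------
    NoInteriorMaximumError
        If the empirical maximum is the first or last sampled point, so no
        interior maximum is bracketed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(products, dtype=float)
    if x.size < n_local:
        raise ValueError(f"need at least {n_local} points")
    i_max = int(np.argmax(y))  # argmax takes the first of equal maxima
    if i_max in (0, x.size - 1):
        raise NoInteriorMaximumError(
            f"maximum at boundary point x={x[i_max]:.3f}"
        )
    order = np.argsort(np.abs(x - x[i_max]), kind="stable")[:n_local]
    xs, ys = x[np.sort(order)], y[np.sort(order)]

    coeffs, cov = np.polyfit(xs, ys, 2, cov=True)
    a, b, _ = coeffs
    if a >= 0:
        raise NoInteriorMaximumError("local fit is not concave")
    x_v = -b / (2.0 * a)
    # vertex gradient w.r.t. (a, b, c): (b/(2a^2), -1/(2a), 0)
    g = np.array([b / (2.0 * a * a), -1.0 / (2.0 * a), 0.0])
    var = float(g @ cov @ g)
    return JobMaximum(float(x_v), float(np.sqrt(max(var, 0.0))), int(n_local))


def stoichiometry_from_xmax(
    x_max: float,
    snap_tolerance: float = SNAP_TOLERANCE,
    max_denominator: int = 4,
) -> tuple[Fraction | float, float]:
    """Zn:peptide ratio implied by the Job maximum, x/(1-x).

    If ``x_max`` lies within ``snap_tolerance`` of a fraction n/(n+m) with
    small n, m (ratio n Zn : m peptide, denominators up to
    ``max_denominator``), the reduced integer ratio is returned as a
    :class:`fractions.Fraction`; otherwise the real ratio.  The second
    element is always the real-valued ratio.
    """
    if not 0.0 < x_max < 1.0:
        raise ValueError("x_max must lie strictly inside (0, 1)")
    ratio = x_max / (1.0 - x_max)
    best = None
    for n in range(1, max_denominator + 1):
        for m in range(1, max_denominator + 1):
            fr = Fraction(n, m)
            x_ideal = fr.numerator / (fr.numerator + fr.denominator)
            err = abs(x_max - x_ideal)
            if err <= snap_tolerance and (best is None or err < best[0]):
                best = (err, fr)
    if best is not None:
        return best[1], ratio
    return ratio, ratio
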