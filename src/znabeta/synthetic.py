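"""Seeded synthetic datasets with the statistical structure of the real
experiments, so every analysis stage is testable without instrument data.

The generators mirror the published experimental designs: chemical-shift
titrations of 1.0-1.5 mM peptide over 0.05-10 zinc molar equivalents with
the sample diluting from 600 toward 800 uL as titrant accumulates; Job
series at a fixed 1.0-1.7 mM total concentration; selective-inversion
recovery curves for a slowly exchanging monomer/dimer resonance pair; and
ITC titrations of 2 uL zinc injections into a 0.2 mL peptide cell.  Every
generator is a pure function of its parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibria import SpeciesSystem, dimer_chain_fraction, solve_equilibrium
from .itc import ITCExperiment, injection_heats
from .jobplot import JobSeries
from .magtransfer import ExchangeDataset, ExchangeModel, simulate_inversion_recovery
from .titration import TitrationPoint, TitrationSeries, forward_shift

__all__ = [
    "NoiseSpec",
    "EXTINCTION_A280_TYR",
    "DEFAULT_EQUIVALENTS",
    "gen_titration",
    "gen_job",
    "gen_mt",
    "gen_itc",
    "concentration_from_a280",
]

# Molar extinction coefficient of the single tyrosine (Y10) of the
# amyloid-beta metal-binding domain at 280 nm, M^-1 cm^-1.
EXTINCTION_A280_TYR = 1280.0

# Zinc molar equivalents spanning the published titration design, 0.05-10
# relative to peptide, denser below equivalence where the shifts move most.
DEFAULT_EQUIVALENTS = (
    0.0, 0.05, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 5.0, 7.0, 10.0,
)

INITIAL_VOLUME_UL = 600.0
FINAL_VOLUME_UL = 800.0


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise in the observable's units, plus the seed.

    Identical (sigma, seed) and generator parameters reproduce the dataset
    bit for bit.
    """

    sigma: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_titration(
    Ka: float,
    peptide_mM: float = 1.0,
    zn_equivalents=DEFAULT_EQUIVALENTS,
    reporters: dict[str, tuple[str, float, float]] | None = None,
    noise: NoiseSpec = NoiseSpec(sigma=0.0),
    v0_uL: float = INITIAL_VOLUME_UL,
    v_final_uL: float = FINAL_VOLUME_UL,
) -> TitrationSeries:
    """Synthetic fast-exchange titration series.

    ``reporters`` maps reporter id -> (nucleus, delta_free, delta_bound) in
    ppm; the default is two 1H reporters with 0.30 and 0.15 ppm endpoint
    separations, typical of histidine-region signals on zinc binding.  The
    sample volume grows linearly from ``v0_uL`` to ``v_final_uL`` across the
    schedule, diluting the peptide; zinc equivalents are relative to the
    (diluted) peptide concentration at each point, as when titrating with a
    concentrated stock.
    """
    eqs = np.asarray(zn_equivalents, dtype=float)
    if eqs[0] != 0.0:
        raise ValueError("schedule must start at zero added zinc")
    if np.any(eqs < 0) or np.any(eqs > 10.0):
        raise ValueError("equivalents must lie in [0, 10]")
    if reporters is None:
        reporters = {
            "H6_He1": ("1H", 7.80, 8.10),
            "H14_He1": ("1H", 7.75, 7.90),
        }
    P0 = peptide_mM * 1e-3
    volumes = np.linspace(v0_uL, v_final_uL, eqs.size)
    rng = noise.rng()
    pts = []
    for eq, vol in zip(eqs, volumes):
        pep = P0 * v0_uL / vol
        zn = eq * pep
        shifts = {}
        for rid, (_, dfree, dbound) in reporters.items():
            d = forward_shift(Ka, pep, zn, dfree, dbound)
            shifts[rid] = float(d + rng.normal(0.0, noise.sigma))
        pts.append(TitrationPoint(zn, float(vol), pep, shifts))
    catalog = {rid: nuc for rid, (nuc, _, _) in reporters.items()}
    return TitrationSeries(tuple(pts), catalog)


def gen_job(
    Ka: float,
    total_mM: float = 1.0,
    n_points: int = 11,
    delta_max: float = 0.30,
    noise: NoiseSpec = NoiseSpec(sigma=0.0),
    x_min: float = 0.05,
    x_max: float = 0.95,
) -> JobSeries:
    """Synthetic continuous-variation series for a 1:1 complex.

    At each zinc mole fraction x the totals are Zn = x*C, P = (1-x)*C and
    the shift change is delta_max times the bound fraction from the 1:1
    quadratic.  Noise sigma is in ppm on the shift change.
    """
    C = total_mM * 1e-3
    x = np.linspace(x_min, x_max, n_points)
    pep = (1.0 - x) * C
    zn = x * C
    if Ka > 0:
        a = pep + zn + 1.0 / Ka
        complex_conc = 0.5 * (a - np.sqrt(np.maximum(a * a - 4 * pep * zn, 0.0)))
        dd = delta_max * complex_conc / pep
    else:
        dd = np.zeros_like(x)
    dd = dd + noise.rng().normal(0.0, noise.sigma, size=dd.shape)
    return JobSeries(C, x, dd, pep)


def gen_mt(
    model: ExchangeModel,
    delays,
    noise: NoiseSpec = NoiseSpec(sigma=0.0),
    inverted_site: str = "mono",
) -> ExchangeDataset:
    """Synthetic selective-inversion recovery dataset.

    Noise sigma is a fraction of each channel's equilibrium magnetization
    (per-channel absolute sigma = sigma * M_eq of that channel).
    """
    clean = simulate_inversion_recovery(model, delays, inverted_site)
    rng = noise.rng()
    im = clean.I_mono + rng.normal(0.0, noise.sigma * model.M_eq_m,
                                   size=clean.I_mono.shape)
    idim = clean.I_dimer + rng.normal(0.0, noise.sigma * model.M_eq_d,
                                      size=clean.I_dimer.shape)
    return ExchangeDataset(clean.delays, im, idim, inverted_site)


def gen_itc(
    Ka: float,
    dH: float = -20e3,
    N: float = 1.0,
    cell_peptide_mM: float = 1.0,
    syringe_zn_mM: float = 10.0,
    n_injections: int = 25,
    noise: NoiseSpec = NoiseSpec(sigma=0.0),
    cell_volume: float = 2.0e-4,
    injection_volume: float = 2.0e-6,
    baseline: float = 0.0,
) -> ITCExperiment:
    """Synthetic single-site ITC experiment at the iTC200-class geometry.

    ``dH`` in J/mol (the -20 kJ/mol default is an arbitrary but
    realistic exothermic binding enthalpy); noise sigma is a fraction of
    the largest |heat|.
    """
    exp0 = ITCExperiment(
        syringe_zn=syringe_zn_mM * 1e-3,
        cell_peptide=cell_peptide_mM * 1e-3,
        heats=np.zeros(n_injections),
        cell_volume=cell_volume,
        injection_volume=injection_volume,
    )
    q = injection_heats(Ka, dH, N, exp0, baseline=baseline)
    sigma_abs = noise.sigma * float(np.max(np.abs(q))) if q.size else 0.0
    q = q + noise.rng().normal(0.0, sigma_abs, size=q.shape)
    return ITCExperiment(
        syringe_zn=exp0.syringe_zn,
        cell_peptide=exp0.cell_peptide,
        heats=q,
        cell_volume=cell_volume,
        injection_volume=injection_volume,
    )


def concentration_from_a280(absorbance: float, path_cm: float = 1.0) -> float:
    """Peptide concentration (M) from A280 via the Y10 extinction coefficient."""
    if absorbance < 0:
        raise ValueError("absorbance must be non-negative")
    if path_cm <= 0:
        raise ValueError("path length must be positive")
    return absorbance / (EXTINCTION_A280_TYR * path_cm)


def dimer_fraction_at(Ka_mono: float, Kdim: float, P_total: float,
                      Zn_total: float) -> float:
    """Convenience: dimer chain fraction at one condition."""
    st = solve_equilibrium(SpeciesSystem(Ka_mono, Kdim, P_total, Zn_total))
    return dimer_chain_fraction(st)
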