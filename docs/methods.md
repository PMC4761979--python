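# Methods

`znabeta` implements the quantitative layer of a zinc-induced
amyloid-beta dimerization study: four experiment-level analyses
(chemical-shift titration, continuous variations, selective-inversion
magnetization transfer, single-site ITC) and one model that ties them
together (the coupled binding/dimerization equilibrium). This note
records the models, their assumptions, the numerical choices, and what
the synthetic-data generators do and do not emulate.

## The coupled equilibrium model

Species: free peptide chain P, free Zn²⁺, the monomeric complex PZn, and
the zinc-bridged dimer P₂Zn in which two chains share one zinc ion
coordinated through the ¹¹EVHH¹⁴ interface residues of both chains.

    P + Zn  ⇌ PZn    Ka_mono = [PZn] / ([P][Zn])        (M⁻¹)
    PZn + P ⇌ P₂Zn   Kdim    = [P₂Zn] / ([PZn][P])      (M⁻¹)

Mass balances (chains and zinc):

    [P] + [PZn] + 2[P₂Zn] = P_total
    [Zn] + [PZn] + [P₂Zn] = Zn_total

Assumptions: the dimer stoichiometry is fixed at two chains / one zinc
(P₂Zn); higher oligomers, 2:2 complexes, zinc–buffer competition and
precipitation are outside the model. The "dimer fraction" is defined on
chains, 2[P₂Zn]/P_total, because both chains of a dimer contribute the
dimer-specific resonances, so intensity-based percentages count chains.

**Solver.** The two balances are solved for (ln[P], ln[Zn]) with a damped
Newton iteration (step halving on the residual max-norm). Log variables
keep the concentrations positive without constraints; the analytic 2×2
Jacobian makes each step exact. Default relative tolerance 1e-12 on
max(P_total, Zn_total); start point: half of each total; iteration cap
200 with a solver-failure error carrying the last residuals. Zn_total = 0
and Ka_mono = 0 short-circuit to the closed form. The solver is
deterministic. A brute-force 2-D grid scan over the free concentrations
serves as the oracle in the tests, and Kdim = 0 is checked against the
1:1 quadratic.

**From exchange rates to Kdim.** Slow monomer⇌dimer exchange with
effective rates k_m→d and k_d→m satisfies detailed balance
k_m→d·f_mono = k_d→m·f_dimer, so the equilibrium dimer chain fraction is
f_dimer = k_m→d/(k_m→d + k_d→m). The measured k_m→d is treated as
condition-specific (pseudo-first-order at the 2.3 mM measurement
concentration); no microscopic second-order rate is extracted, and
whether the published rate folds in partial zinc occupancy is not
knowable from the rates alone — the calibration below is one consistent
reading. `calibrate_kdim` finds the Kdim whose equilibrium solution
reproduces that fraction at the measurement conditions (2.3 mM peptide,
half-equivalence zinc) by bisection on log₁₀Kdim — the fraction is
strictly increasing in Kdim, so the root is unique; unattainable targets
(zinc-limited) raise an infeasibility error. The calibrated model then
predicts the fraction at any other concentration
(`predict_dimer_curve`), which is how the observed rise from ~1.6% at
0.2 mM to ~39% at 6.5 mM emerges from two constants.

## Chemical-shift titration (fast exchange)

Observed shift per reporter: δ_obs = δ_free + (δ_bound − δ_free)·f_bound
with f_bound from the 1:1 quadratic (the dimer is a few percent at
titration concentrations and is neglected in the shift model).
`fit_binding` is a global fit: one shared Ka (fitted as log₁₀Ka, bounds
[1, 10⁸] M⁻¹), per-reporter endpoints free. Initialization: a 60-point
log-spaced Ka grid, solving the endpoints linearly at each grid value
(δ_obs is linear in the endpoints at fixed Ka), then bounded
least-squares refinement; Ka uncertainty from the covariance via the
delta method on log₁₀Ka. Reporters whose total excursion is below the
noise floor (default 0.005 ppm for ¹H, configurable) are excluded; if
none survive, a no-binding error is raised rather than a garbage fit.

Dilution is handled exactly: each point carries its sample volume, and
the peptide total is scaled by V₀/V. A regression test generates a
strongly diluted series and shows the correction removes the Ka bias
that ignoring it introduces.

**Scatchard diagnostic.** For a 1:1 isotherm, Δδ/[Zn]_free =
Ka·Δδ_max − Ka·Δδ — exactly linear with slope −Ka. Free zinc is computed
from the fitted Ka (peptide and zinc are comparable in concentration, so
total zinc is not a valid proxy). The R² of the line is the reported
linearity statistic; multi-site data break the linearity, which the
tests demonstrate with a planted two-site mixture.

**Site mapping.** `shift_rmsd_profile` computes per-residue weighted
RMSDs between free and bound assignment tables, matching on (residue,
atom, nucleus). ¹³C differences are weighted 0.25 relative to ¹H — the
conventional heteronuclear scaling, chosen because ¹³C shift ranges are
roughly four times wider; unmatched nuclei are counted per residue, not
dropped silently.

## Continuous variations (Job plot)

At fixed total concentration C the product Δδ·[P]₀ is proportional to
the complex concentration, so its maximum in the zinc mole fraction x
locates the stoichiometry (x = 0.5 → 1:1). The maximum is located by a
quadratic vertex fit over the 5 points nearest the empirical maximum
(ties broken toward smaller x) — robust to the flattening of the curve
at weak binding, which lowers but does not shift a 1:1 maximum. The
vertex uncertainty is propagated from the polynomial covariance.
Stoichiometry reporting snaps x_max to a small-integer ratio n:m
(denominators ≤ 4) when within 0.05 of the ideal fraction n/(n+m),
otherwise reports the real ratio x/(1−x). A boundary maximum raises an
error instead of returning an extrapolated vertex.

## Magnetization transfer (two-site longitudinal exchange)

Longitudinal magnetizations of the monomer and dimer resonances obey

    d/dt (m − m_eq) = −L (m − m_eq),
    L = [[R1_m + k_md, −k_dm], [−k_md, R1_d + k_dm]]

with the closed-form solution m(t) = m_eq + exp(−Lt)(m0 − m_eq). The
2×2 exponential is evaluated spectrally, with eigenvalues
λ± = ½(a+d) ± ½√((a−d)² + 4·k_md·k_dm); (near-)degenerate eigenvalues
switch to the defective-matrix limit e^{−λt}(I − t(L−λI)) rather than
failing. The closed form is verified in the tests against both a
step-wise RK4 integrator (dt = 1e-5 s) and `scipy.linalg.expm` over
randomized models.

Selective inversion starts the inverted site at (1 − 2·η)·M_eq, where
η ∈ [0,1] is the inversion efficiency — a perfect pulse lands at −M_eq,
a failed one leaves equilibrium untouched — and the other site at its
M_eq. `fit_exchange` fits both trajectories jointly: k_md, k_dm, a
shared R1 (separate R1s are optional but poorly identified at realistic
delay counts), the total equilibrium magnetization, and η as a nuisance
parameter bounded [0.7, 1.0]. Detailed balance is built in: the M_eq
split is tied to the rate ratio, never fitted independently.
Non-identifiable designs (delays all off the exchange timescale) are
flagged through the condition number of the covariance (threshold 1e10).

## ITC (single-site Wiseman isotherm)

Overflow-cell convention (MicroCal-style, stated explicitly because
instrument software is opaque about it): each injection of volume v into
the cell of volume V₀ displaces mixed solution, so the retained fraction
per injection is d = 1 − v/V₀; after i injections the cell holds
P₀·dⁱ peptide and Zn_syr·(1 − dⁱ) zinc. With N sites per peptide the
1:1 quadratic gives the bound concentration B_i and the heat is

    q_i = V₀·ΔH·(B_i − B_{i−1}·d) + baseline

— the expelled volume carries away complex without generating heat, and
the baseline is a constant heat of dilution. `fit_itc` fits
(log₁₀Ka, ΔH, N, baseline) and reports the c-value Ka·N·[P]cell,
flagging fits with c outside [1, 1000] as low-confidence because the
isotherm shape then under-determines Ka.

## Synthetic data

The generators emulate the published experimental designs: titrations of
1.0–1.5 mM peptide over 0.05–10 zinc equivalents with the sample volume
growing linearly from 600 to 800 μL (equivalents are relative to the
diluted peptide, as when titrating from a concentrated stock); Job
series at a fixed 1.0–1.7 mM total; 12 log-spaced mixing delays over
1 ms–1 s around the ~40 s⁻¹ exchange timescale with shared R1 = 1.5 s⁻¹;
ITC with 2 μL injections into a 0.2 mL cell, 1.0 mM peptide and 10 mM
zinc syringe (25 injections ≈ 2.2 equivalents, c ≈ 13). ΔH for ITC
synthesis defaults to −20 kJ/mol — a realistic exothermic value, free
because the source reports no enthalpy. Titration endpoint shifts
default to two ¹H reporters with 0.30 and 0.15 ppm excursions, typical
of histidine-region signals on zinc binding.

Noise is additive Gaussian only — σ = 0.003 ppm on ¹H shifts, 1% of each
channel's M_eq for magnetization transfer, 1% of the largest |heat| for
ITC — and every generator is a pure, bit-reproducible function of
(parameters, seed); the per-test default seed is 42. Not emulated: raw
FIDs and peak picking, line broadening and intermediate exchange,
heteroscedastic or drifting baselines, peptide precipitation at high
concentration, and zinc–buffer competition. Passing recovery tests
therefore show that the estimators are correct and well-conditioned at
the published designs, not that real spectra are free of those
systematics.

## Problem sizes and runtime

All analyses are desk-scale: 14-point titrations, 11-point Job series,
12-delay exchange datasets, 25-injection isotherms; the equilibrium
solver converges in <20 Newton steps. The full test suite (including a
100-realization exchange-recovery Monte Carlo and grid-scan oracles)
runs in a few seconds; `scripts/acceptance.py` in well under a minute.

## Known limitations

- The equilibrium model stops at the dimer; the oligomerization the
  dimer seeds (and the precipitation thresholds that accompany it) is
  out of scope, so predictions above ~8 mM extrapolate a two-step model
  into a regime where higher-order species exist.
- The 0.5 ITC stoichiometry reported elsewhere for the H6R variant
  (consistent with a 2:1 chain:zinc complex at calorimeter conditions)
  is not reconciled with the 1:1 monomeric-complex step here; the model
  keeps N free in fitting and fixed at the two-step scheme in the
  equilibrium module.
- Ka uncertainties are covariance-based (delta method on log₁₀Ka);
  bootstrap resampling is not implemented.
- The Job analysis assumes a single dominant complex; overlapping
  equilibria deform the curve in ways the quadratic vertex fit does not
  deconvolve.
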