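# Methods

`cosolvency` analyses equilibrium solubility grids of a crystalline solute
in binary aqueous cosolvent blends — the shipped study system is piperine
in Transcutol-HP (diethylene glycol monoethyl ether, THP) + water — through
four stages: unit conversion, ideal-solution and mixing thermodynamics,
Hansen solubility parameter (HSP) screening, and correlation with five
cosolvency models.

## Data model and unit conversion

A dataset is a set of records (m, T, x_e): cosolvent mass fraction of the
solute-free solvent blend, absolute temperature, and mole-fraction
solubility. Raw measurements in mg solute per g solvent convert by mole
bookkeeping over 1 g of solvent split into m g cosolvent and (1 − m) g
water:

    x_e = (m1/M1) / (m1/M1 + m2/M2 + m3/M3),   m1 = raw/1000 g.

"mg per g" means per gram of *solvent*, not of solution; that convention
reproduces the literature conversion 185.29 mg/g → x_e = 8.01 × 10⁻² for
piperine in pure THP exactly. The packaged molar masses are the study's
tabulated values (285.34, 134.17, 18.07 g/mol). Water's tabulated
18.07 g/mol is almost certainly a misprint of ≈18.02, but it is kept as
printed for fixture fidelity — the worked conversions agree at 3
significant figures under either value — and is configurable through
`MolarMasses`.

The packaged fixture is the study's full 11 × 5 grid (m = 0.0–1.0 by 0.1;
T = 298.2–318.2 K by 5 K). Grid completeness and the presence of both pure
solvents are enforced only by the operations that need them (the mixture
models); single-composition analyses accept partial data.

## Ideal solubility and activity coefficients

The ideal mole-fraction solubility follows from the solute's fusion
properties (for piperine: T_fus = 404.88 K, ΔH_fus = 32.69 kJ/mol,
ΔC_p = 80.74 J/(mol·K), with R = 8.314 J/(mol·K)):

    ln x_idl = −ΔH_fus (T_fus − T)/(R T_fus T)
               + (ΔC_p/R) [(T_fus − T)/T + ln(T/T_fus)],

which is 1 at T = T_fus and strictly increasing below it. The solute
activity coefficient is γ_i = x_idl / x_e: γ_i ≫ 1 signals strongly
unfavourable solute–solvent interaction relative to the ideal solution
(piperine in water: γ ≈ 5 × 10³), γ_i near or below 1 a near-ideal or
favourable one (piperine in THP: γ = 0.65–1.06).

## Mixing thermodynamics

For the saturated ternary composition (x1 solute, x2 cosolvent, x3 water;
the solvent species split 1 − x1 in their solute-free mole ratio):

    ΔG_id = RT Σ x ln x ≤ 0,  ΔS_id = −R Σ x ln x ≥ 0,  ΔH_id = 0,

with 0·ln 0 := 0. Only the solute's activity coefficient is measurable
from a solubility grid — no solvent–solvent interaction parameters can be
estimated from it — so the excess Gibbs energy keeps the solute term only:

    G_E = RT x1 ln γ_i,

with the solvent species treated as ideal. The excess enthalpy comes from
Gibbs–Helmholtz, H_E = −T² ∂(G_E/T)/∂T, evaluated by fitting G_E/T as a
linear function of 1/T across each composition's temperature series (the
fitted slope is H_E, constant over the series). The fitted form is used
rather than pointwise finite differences for noise robustness; a central
finite-difference estimator (`excess_enthalpy_fd`) is exposed as a
cross-check and agrees to 1 × 10⁻⁶ relative on smooth series sampled
densely enough (the truncation error of a central difference at step h is
O((h/T)²), so the 5 K study spacing alone resolves H_E only to ≈3 × 10⁻⁴
relative).

Net quantities are G_mix = ΔG_id + G_E and H_mix = H_E; the mixing entropy
is recovered from the exact identity S_mix = (H_mix − G_mix)/T, so every
record satisfies G = H − T·S by construction (asserted to 1 × 10⁻⁶
relative in the tests).

## Hansen solubility parameters

Totals combine components as δ² = δ_d² + δ_p² + δ_h²; solvent blends take
the linear mix δ_mix = α δ₁ + (1 − α) δ₂. α is nominally the cosolvent
volume fraction, but the study's printed endpoints (24.04 MPa^1/2 at
m = 0.9, 45.16 at m = 0.1) reproduce exactly only with α equal to the
*mass* fraction m, so α = m is the default convention; callers holding a
density table can pass true volume fractions. Only total δ values are
published for this system (piperine 22.30, THP 21.40, water 47.80
MPa^1/2), so component-level arithmetic is exercised on synthetic values.
Ranking candidate solvents by |δ − δ_solute| predicts the solubility
maximum in pure THP correctly.

## Cosolvency models

Five models are fit per dataset, all on ln x:

1. **Van't Hoff** per composition: ln x = a + b/T by ordinary least
   squares on 1/T.
2. **Apelblat** per composition: ln x = A + B/T + C ln T. The model is
   linear in (A, B, C), so "nonlinear regression" reduces to exact least
   squares on the regressors {1, 1/T, ln T}. Over a 20 K window these are
   nearly collinear (condition numbers ≳10⁹); the design is
   column-equilibrated before solving, and the fit exposes the condition
   number. Individual coefficients are not meaningful under such
   collinearity — predictions and RMSD are.
3. **Yalkowsky–Roseman**: log₁₀ x = m log₁₀ x₁ + (1 − m) log₁₀ x₂, a
   parameter-free log-linear blend of the measured pure-solvent
   solubilities.
4. **Jouyban–Acree**: the log-linear rule plus interaction terms
   (m₁m₂/T) Σᵢ Jᵢ (m₁ − m₂)ⁱ, i = 0, 1, 2, estimated by no-intercept
   least squares on the mixture-point residuals about the measured
   pure-solvent baseline. Powers with p > 0.05 are dropped (worst first)
   and the model refit; at least one power is always retained, and an
   exactly zero interaction snaps to J = 0 so the model degenerates to the
   log-linear rule identically. %RMSD is over the mixture points (the pure
   rows are reproduced by construction).
5. **Jouyban–Acree–Van't Hoff**: the same interaction structure on top of
   Van't Hoff-smoothed pure-solvent terms, fit in two stages — pure-solvent
   Van't Hoff fits first, then the interaction regression on residuals.
   Two stages (rather than one joint regression) because the pure-solvent
   coefficients of the trained published model equal the pure-solvent
   Van't Hoff rows exactly. %RMSD spans the whole grid, since the pure
   rows are now modelled too.

Diagnostics: R² is reported on the regression (ln x) scale and

    %RMSD = 100 · sqrt( mean[ ((x_obs − x_pred)/x_obs)² ] )

on the mole-fraction scale — the combination that reproduces the published
per-composition RMSDs from the published coefficients. Model comparison
ranks by average %RMSD with ties broken by fewer fitted coefficients, then
name.

On the packaged piperine grid the interaction regressions retain a single
positive J₀ ≈ +17.5 K. The study's trained model prints J = −14.43 K; the
rounded published grid cannot reproduce that value (its mixture residuals
about the log-linear baseline are uniformly positive, forcing a positive
J₀), so the printed interaction coefficient and its 0.42% RMSD are treated
as artefacts of unrounded source data and are not asserted anywhere.

## Synthetic data generator

Grids are drawn from the Jouyban–Acree–Van't Hoff law with additive
Gaussian noise of standard deviation σ on ln x (multiplicative lognormal
on x), matching the relative-error structure the %RMSD metric assumes.
Defaults mirror the study conditions: the 11 × 5 (m, T) grid, the trained
coefficients A₁ = −0.21, B₁ = −696.21 K, A₂ = −4.45, B₂ = −2093.60 K,
J = (−16.42 K,), and σ = 0.01 — a 1% relative scatter consistent with the
sub-2% model RMSDs such data exhibit. Generation is deterministic per
(config, seed) to byte-identical CSV. The generator emulates the smooth
log-linear-plus-interaction structure and multiplicative noise of real
shake-flask grids; it does not emulate analytical (HPLC) error structure,
inter-day variability, temperature-dependent noise, or outliers, so
passing recovery tests demonstrate estimator correctness under the assumed
model, not robustness to those artefacts.

Estimator calibration checks: at σ = 0 refits recover all generating
coefficients to 1 × 10⁻⁸; at σ ∈ {0.005, 0.01} the mean recovered J₀ over
200 seeded replicates stays within two standard errors of truth, and the
Van't Hoff slope scatter under fixture perturbation matches the analytic
OLS standard error within 30%.

## Numerical choices and degenerate inputs

- Least squares throughout is exact linear algebra (QR/SVD), never
  iterative optimisation; fitters agree with closed-form, grid-search and
  exact-rational normal-equation oracles to 1 × 10⁻⁸ relative on small
  instances.
- Validation errors name the offending row or (m, T) cell.
- Van't Hoff needs ≥3 distinct temperatures; Apelblat ≥4 points and a
  rank-3 design; Gibbs–Helmholtz ≥2 temperatures; mixture models a
  complete grid with both pure solvents.
- Degenerate p-values in the interaction elimination (an exactly
  interpolating fit) are handled by a zero-residual branch that prunes
  numerically zero coefficients instead of consulting p-values.
- The analysis pipeline is deterministic: identical inputs produce
  byte-identical report files. Report tables round as published work does
  (solubilities 3 significant figures, log-solubilities and %RMSD 2
  decimals).

## Known limitations

- The excess terms ignore solvent non-ideality entirely; G_E and H_E are
  solute-interaction summaries, not full Wilson/NRTL excess models.
- H_E is constant per composition by construction of the linear
  Gibbs–Helmholtz fit; curvature of G_E/T in 1/T is not modelled.
- HSP blending is linear in mass fraction; no density correction or
  component-wise (δ_d, δ_p, δ_h) mixing for blends.
- Published coefficient tables fitted on unrounded source data are not
  exactly recoverable from a grid printed to 3 significant figures;
  small-magnitude intercepts are the most affected (deviations up to
  ≈3.4% where slopes stay within 1.5%).
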