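# Methods

## Scope and model overview

`methanocosm` analyses sealed-bottle (microcosm) methanogenesis assays in
which a defined carbohydrate dose is incubated with an inoculum and the
headspace gases, dissolved organic acids, pH and residual substrate are
followed over roughly four months. Three model layers are involved:

1. **Electron-partitioned stoichiometry.** An organic donor C_nH_aO_bN_c
   carries `d = 4n + a − 2b − 3c` electron equivalents per mole. A fraction
   `fs` of these is invested in cell synthesis (biomass as C5H7O2N, 20 e⁻-eq
   and 113 g per mole) and `fe = 1 − fs` in energy; with CO2 as the terminal
   acceptor the energy electrons appear as methane at 8 e⁻-eq per mole, so
   the theoretical methane yield is `d·fe/8` mol per mole of donor. CO2,
   water, ammonium and bicarbonate close the element and charge balances.
   The net biomass yield is `Y = fs·113/(20·8) = 0.706·fs` g cells per g COD
   (COD at 8 g per e⁻-eq). Decay is neglected and ammonium is the nitrogen
   source, so for nitrogen-free donors the NH4+/HCO3− coefficients are
   negative: cell nitrogen is drawn from the medium. Coefficients are stored
   signed on a product-side convention (positive = produced) and the
   pretty-printer moves negatives to the reactant side; this keeps the
   algebra checkable by a single element/charge balance function, which the
   constructor asserts to < 1e−9 on every reaction it builds.

2. **Cumulative-methane kinetics.** The modified Gompertz curve
   `y(t) = A·exp(−exp(μm·e/A·(λ − t) + 1))` with asymptote `A`
   (µmol CH4 per g substrate carbon), maximum rate `μm` (µmol g⁻¹ C d⁻¹,
   the slope at the inflection where y = A/e) and lag `λ` (d). Slow,
   non-sigmoidal producers get an ordinary least-squares line instead.

3. **Carbonate speciation and carbon ledger.** Diprotic closed-form
   ionization fractions (pK1 = 6.35, pK2 = 10.33 at 25 °C) partition DIC;
   Henry's law (KH = 0.0339 mol L⁻¹ atm⁻¹) links headspace CO2 to dissolved
   H2CO3*; the ideal-gas law at the 1 atm / 25 °C reporting convention
   converts headspace mole fractions to moles. Each sampling day's carbon is
   booked into CH4-C, biogenic headspace CO2-C, biogenic DIC-C, buffer-C,
   the three quantified acids (acetic 2 C, formic 1 C, lactic 3 C), residual
   substrate, and biomass as the closing residual.

## Fitting: initialization, bounds, convergence

The Gompertz fit minimizes the residual sum of squares with
`scipy.optimize.least_squares` (trust-region reflective, i.e. a bounded
Levenberg–Marquardt-type solver; `xtol = ftol = gtol = 1e−12`).
Initialization is chosen for sigmoid data with long lags: `A0 = max(y)`,
`λ0` = latest time with `y < 0.05·max(y)` (0 if none), `μm0` = largest
positive finite-difference slope. Bounds `A ∈ (0, 10·max(y)]`,
`μm ∈ (0, ∞)`, `λ ∈ [0, max(t)]` prevent sign-flipped optima. R² is defined
as `1 − SSR/SST` for both model families. Non-convergence is reported via a
flag, not an exception; an all-zero series raises a dedicated
no-production error so degenerate controls fail loudly rather than fit
nonsense. The standard error of `A` comes from the Gauss–Newton covariance
`(JᵀJ)⁻¹·s²`.

Per treatment, all replicate points are pooled for the reported parameter
set, and each replicate is also fitted alone to attach a standard deviation
to `A`. The automatic model choice keeps the Gompertz fit when it converges
with `R² ≥ 0.6` and `se(A) < A`, else reports the linear fit; both the
threshold and the model can be forced.

Consolidated sugar-group rates (five-carbon vs six-carbon) are the OLS
slope of the pointwise-mean curve from day 0 through the first sampling at
95 % of its maximum. Fitting the whole window instead would dilute the
slope with plateau points and — because the five-carbon asymptote is larger
while its rise is slower — can invert the group ordering; the windowed
slope measures the production phase, which is what a "rate" means here.

## Synthetic data generator

The generator emulates the study design the analysis targets: triplicate
bottles, 10 mM substrate dose, 100 mL liquid / 60 mL headspace, 128-day
incubation, headspace gas sampled every 5 days and liquids on days
{2, 46, 83, 128}. Per treatment it uses the kinetic parameter sets a
128-day coal-microcosm incubation typically yields (sugar asymptotes
5041–7339 µmol g⁻¹ C, rates 151–1375 µmol g⁻¹ C d⁻¹, lags 35–42 d; a slow
linear disaccharide at 218 µmol g⁻¹ C; an acetate-fed control with a 65-day
lag). Structure it reproduces:

- cumulative CH4 = Gompertz mean + Gaussian noise with s.d.
  `sd0·(1 − 0.5·t/128)` (default `sd0` = 200 µmol g⁻¹ C), truncated at 0 and
  made nondecreasing by a running maximum — replicate scatter shrinks as
  bottles approach their plateau;
- replicate lags jittered uniformly ±3 d;
- CO2 tied to CH4 by the fs = 0.2 reaction's CO2/CH4 molar ratio and
  partitioned between headspace and liquid by Henry's law at the generated
  pH, so ledger round-trips are physically consistent;
- monosaccharides exhausted by the day-2 liquid sampling, the disaccharide
  by day 46; acids high at day 2 (acetate ≈ 1.1–1.9 mol per mol substrate),
  dipping mid-incubation and re-accumulating late; sugar-fed pH 5.7–6.5,
  controls 6.5–7.2.

A fixed seed makes the dataset byte-identical. What the generator does
*not* emulate: mechanistic fermentation dynamics, community succession,
coal-derived carbon release, CO2 sorption onto the solid phase, or
correlated replicate noise — so passing recovery tests demonstrate the
fitter and ledger are correct on data with the assumed structure, not that
real bottles obey the Gompertz model.

Parameter-recovery studies use a stripped companion
(`simulate_triplicate`): Gompertz mean plus homoscedastic zero-mean noise
truncated at zero, no lag jitter and no running maximum, so the study
measures the fitter against a known truth rather than the jitter. At noise
s.d. 200 and 100 simulated triplicates the median fitted `A` lands within
a fraction of a percent of truth and median `μm` within a few percent even
for the steepest riser (rise time ≈ 4.4 d against a 5-d sampling grid).

## Carbon ledger conventions

The ledger must satisfy two constraints simultaneously: buffer-derived
inorganic carbon is subtracted before CO2 is booked as biogenic, and the
pools must sum exactly to the carbon added (substrate + buffer). It
therefore carries the buffer as its own pool, fixed at the dosed NaHCO3
carbon, netting it first against measured DIC and any remainder against
headspace CO2. Biomass is the signed closing residual: the conventional
batch accounting, which overestimates biomass whenever carbon leaves by an
unmeasured route; a negative residual is flagged (`closure_ok = False`),
never clipped, and the sum identity holds for every input. Trace acids and
alcohols are excluded by default (optional columns default to zero).

For a bottle constructed exactly from the fs = 0.2 glucose reaction, the
ledger books 20 % of the substrate carbon as biomass: cells carry
`d·fs/20·5 = 1.2` C per glucose, of which 0.24 C is drawn from bicarbonate,
and the buffer netting reproduces that split exactly.

## Defaults and tunables

| parameter | default | units | rationale |
|---|---|---|---|
| fs / fe | 0.2 / 0.8 | — | standard anaerobic-methanogen synthesis fraction |
| pK1, pK2 | 6.35, 10.33 | — | fresh-water carbonic acid at 25 °C; van't Hoff correction available |
| KH | 0.0339 | mol L⁻¹ atm⁻¹ | CO2 Henry constant at 25 °C |
| gas reporting | 1 atm, 25 °C | — | assay reporting convention; incubation T (30 °C) kept separately |
| liquid / headspace | 0.1 / 0.06 | L | plausible serum-bottle split; config-overridable placeholders |
| buffer | 1 | mg L⁻¹ NaHCO3 | nominal medium recipe; almost no buffering capacity, so a warning is emitted when defaulted |
| noise sd0 / decay | 200 / 0.5 | µmol g⁻¹ C | replicate scatter at gas-production onset, halving by day 128 |
| Gompertz/linear switch | R² ≥ 0.6 and se(A) < A | — | separates sigmoidal sugars from slow linear producers |

Conversion efficiency exposes two bases (the partitioned `d·fe/8` yield and
the complete-conversion `d/8` limit) and two unit bridges (mol per mol, and
µmol per g substrate carbon via `coeff_ch4/(12.011·n)·10⁶`); none is
adjudicated as "the" efficiency because reported field values are ambiguous
between them.

## Known limitations

- Equilibrium carbonate chemistry only; no kinetics, ionic-strength
  activity corrections, or CO2 sorption on the solid phase (a recognized
  sink in coal systems — the ledger would book sorbed CO2 as biomass).
- Biomass-by-difference inherits every measurement bias in the other pools.
- The Hartley F-max critical value is a user-supplied table lookup
  (default 39.2, the four-group small-sample value); no interpolation is
  attempted.
- Replicate uncertainty on Gompertz parameters is the spread of per-replicate
  fits; no bootstrap or Bayesian intervals.

## Problem sizes used in the checks

Test and acceptance runs use 500 fuzzed reactions for the balance property,
100 simulated triplicate datasets per treatment (27 gas samplings × 3
replicates each) for parameter recovery, and the trimmed three-treatment
scenario for pipeline round-trips; the full default scenario (eight
treatments) runs end to end in a few seconds.
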