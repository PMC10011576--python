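# Methods

`acidnit` implements the quantitative chain used to ask how acidification of
estuarine and coastal waters changes nitrification and the N₂O it produces:
¹⁵N-tracer rate estimation, carbonate-system speciation for treatment design,
N₂O isotopomer source partitioning, acidification–response curve fitting, and
global emission upscaling. This note records the models, the assumptions they
make, the numerical choices, and what the synthetic-data generator does and
does not emulate.

## ¹⁵N tracer rate estimation (`acidnit.tracer_rates`)

A vessel of volume *V* (default 4 L) is spiked with ¹⁵NH₄Cl to an atom
fraction

    F = [¹⁵NH₄⁺] / ([¹⁴NH₄⁺] + [¹⁵NH₄⁺]),

kept below ~0.2 so that the spike does not perturb the ambient pool.
Nitrification moves ¹⁵N into the combined NO₃⁻ + NO₂⁻ (NOₓ⁻) pool; the
two-point estimator over the incubation interval [t₀, t₁] is

    R_nit = [ r₁·[NOₓ⁻]₁ − r₀·[NOₓ⁻]₀ ] / (t₁ − t₀) / F,

with r the ¹⁵N atom fraction of the NOₓ⁻ pool. Inputs are in µmol L⁻¹ (the
working unit of colorimetric nutrient analysis); the output is scaled ×1000
to nmol L⁻¹ h⁻¹. The estimator assumes F is constant over the incubation
(no significant NH₄⁺ remineralisation over 24 h — reasonable for a ≤20%
spike and the short incubation) and linear accumulation; for multi-timepoint
protocols a least-squares slope of r(t)·[NOₓ⁻](t) against t is provided
(`nitrification_rate_regression`), plus a plain NOₓ⁻-slope rate for
enrichment cultures where all NOₓ⁻ accumulation is nitrification.

N₂O produced from the labelled NH₄⁺ pool appears as the mass-45 (one ¹⁵N)
and mass-46 (two ¹⁵N) isotopologues. Two estimators of the N-atom production
rate (pmol N₂O-N L⁻¹ h⁻¹) are provided:

* **Isotopologue formula** (`n2o_rate_isotopologue`), implemented verbatim
  as used in the field:

      R = (1/F) · [ Δ45/Δt + 2·(Δ46/Δt)·(1/F) ] · (1/V).

  Note the 1/F applied *twice* to the mass-46 term. If both N atoms of each
  N₂O molecule are drawn independently from the NH₄⁺ pool (binomial pairing,
  p45 = 2F(1−F), p46 = F²), the expectation of this formula is (2 − F) times
  the true N-atom rate. The factor is documented and tested, not silently
  corrected: published rates computed with this formula can be interpreted,
  and compared, only if the formula is reproduced exactly.
* **Atom balance** (`n2o_rate_atom_balance`), the unbiased diagnostic
  companion: R = (Δ45 + 2·Δ46)/(F·Δt·V), which counts labelled atoms
  directly and recovers the true rate exactly under binomial pairing.

Synthetic benchmarks report both. Negative rates (label decline) are
returned as-is with a `negative` flag — never clamped — so that QC decisions
stay with the analyst.

## Carbonate system (`acidnit.carbonate`)

Speciation uses the constant set appropriate for glass-electrode pH +
coulometric DIC measurements in estuarine/coastal water: K1/K2 of Mehrbach
et al. (1973) as refit by Dickson & Millero (1987) on the seawater pH scale;
K0 of Weiss (1974); KB of Dickson (1990a) converted from the total to the
seawater scale via KS (Dickson 1990b) and KF (Dickson & Riley 1979); KW of
Millero (1995); total boron from the Uppström (1974) ratio. Alkalinity is
truncated to carbonate + borate + water terms — nutrient alkalinity is
negligible at the ≤10 µM NH₄⁺ of these incubations — and pCO₂ is treated as
equal to fugacity (<0.5% error at 1 atm). All quantities are µmol per kg of
solution; incubation bookkeeping that needs per-litre values may use the
1 L ≈ 1 kg approximation, which the I/O layer flags.

The forward direction (pH + DIC → TA, pCO₂, species) is closed-form through
the ionization fractions at [H⁺] = 10^(−pH). Inverse solves — pH from
(TA, DIC) and the full state from (TA, pCO₂) — bracket the pH root on
[2, 12] and refine with Brent's method (xtol 10⁻¹⁰ pH). TA is strictly
monotone in pH at fixed DIC or fixed pCO₂ over this bracket, so the root is
unique; a target that cannot be bracketed raises `NoSolutionError` rather
than extrapolating. Internally everything is on the seawater pH scale; an
explicit NBS↔SWS conversion (fH of Takahashi et al. 1982) is available but
off by default, because electrode calibrations vary and silent rescaling of
measured pH would be worse than documented pass-through.

The pCO₂ × pH factorial helper reproduces the treatment-design logic of
decoupling experiments: bubbling pins pCO₂, automatic acid/base dosing pins
pH, and the implied DIC/TA of each of the four cells (400/800 µatm × 8.1/7.8)
follows in closed form, along with the alkalinity adjustment the dosing must
supply.

## Isotopomer source partitioning (`acidnit.isotopomer`)

The site preference SP = δ¹⁵Nᵅ − δ¹⁵Nᵝ of emitted N₂O distinguishes
NH₂OH-oxidation-type production (high SP, ≈ +30‰ class) from NO₂⁻ reduction
(nitrifier denitrification + heterotrophic denitrification, SP ≈ 0‰ class).
The fraction from reduction is linear two-endmember mixing on SP alone:

    f_red = (SP_prod − SP_sample)/(SP_prod − SP_red),

clipped to [0, 1] with every clip flagged and counted. δ¹⁸O is carried as
data but not used for apportionment: SP is the pathway-diagnostic axis, and
a dual-isotope mapping would require fractionation parameters the package
does not model (no Rayleigh correction for partial N₂O consumption either —
a known limitation for samples where N₂O reduction is active).

Uncertainty is propagated by Monte Carlo: independent normal draws for the
sample SP and both endmembers, per-draw mixing with clipping, and a summary
(mean, sd, central 95% interval, clip rate) over draws. Draws with crossed
endmembers are excluded and reported via the effective `n_draws`. The
shipped endmember defaults are literature-typical placeholders, marked
non-authoritative; site-specific endmembers should be supplied whenever
available.

## Acidification–response curves (`acidnit.response`)

Each replicate vessel at pH reduction ΔpH (control pH minus treatment pH)
yields a percent change against the *mean* of the control replicates
(treatments and controls are independent triplicates, so per-replicate
pairing would be artificial). The response curve is a polynomial with the
intercept structurally constrained to zero — zero acidification cannot
change the rate, so the origin is a property of the model, not a fitted
parameter. Degree defaults to 2 (configurable 1–3); at degree 1 the
coefficient reduces to the classical zero-intercept slope Σxy/Σx².

The fit is OLS on the monomial design without a constant. Because the null
hypothesis is the identically-zero response, the natural fit statistics are
the uncentered R² and the F-test of all coefficients against zero, which is
what a no-constant OLS reports. Reported per-coefficient standard errors
are HC3 heteroscedasticity-robust: replicate scatter in percent-change data
grows with the response magnitude (multiplicative measurement error), and
classical homoscedastic errors undercover in exactly that regime. An
all-zero response returns the zero curve with p = 1. Evaluation outside the
fitted ΔpH domain warns but proceeds. No multiple-testing correction is
applied across sites; per-curve p-values are reported as is.

The headline evaluation point is ΔpH = 0.21, the average pH decline
observed across estuarine and coastal waters over recent decades.

## Global upscaling (`acidnit.upscale`)

Scenario arithmetic, deliberately simple and linear:

    increase = baseline × nitrifier_share × response,

evaluated at the low and high ends of the response range, then expressed as
a percentage of the 6.9 Tg N₂O-N yr⁻¹ anthropogenic total, rounded half-up
to one decimal. The nitrifier share defaults to 0.5 (nitrifiers contribute
about half of estuarine + coastal N₂O emission). The baseline estuarine +
coastal emission is a required input; the shipped 1.08 Tg N₂O-N yr⁻¹ is a
*reconstructed* placeholder obtained by inverting the published increase
range against the share and response defaults (the inversion brackets it
between ~1.05 and ~1.09 Tg), and is flagged as such — any real assessment
must substitute a sourced inventory value. No spatial resolution and no
uncertainty beyond the low/high range propagation are attempted.

## Synthetic data (`acidnit.synthetic_data`)

The generator's defaults are the study conditions of the emulated design:
4 L vessels, 24 h incubations sampled at start and end (0/5/8/12/24 h for
the enrichment protocol), ambient NH₄⁺ 8 µM + 2 µM ¹⁵NH₄⁺ spike (F = 0.2,
the 20% ceiling), true nitrification rate 100 nmol L⁻¹ h⁻¹ and N₂O
production 40 pmol N L⁻¹ h⁻¹ (mid-range for eutrophic estuarine water), a
multi-site transect of six stations whose generating response curves at
ΔpH = 0.21 span −7.7% to −25.0% (nitrification) and +9.5% to +27.5% (N₂O),
ΔpH ladders within the 0.10–1.05 manipulation range, triplicate vessels,
and the 400/800 µatm × 8.1/7.8 carbonate factorial at 25 °C.

The noise model is multiplicative Gaussian with a default CV of 5% per
observation — an instrument-like error model chosen once, since the
emulated protocols report no explicit error structure. The initial ¹⁵N atom
fraction of the NOₓ⁻ pool defaults to natural abundance (0.00366) rather
than zero; this matters only at extreme precision and is toggleable. All
randomness flows from a single seed; per-site seeds are derived
deterministically from it, so identical seeds give byte-identical CSVs.

What the generator does *not* emulate — and therefore what passing tests do
not show about real data: microbial growth dynamics and community turnover,
NH₄⁺ remineralisation (F is held constant), headspace–liquid N₂O exchange
kinetics, O₂ dynamics, hybrid N₂O formation with only one pool-derived N
atom beyond the simple `single_label` pairing option, and any covariance
between nitrification and N₂O responses within a vessel. Recovery results
on synthetic data demonstrate estimator correctness under the stated model,
not robustness to these real-world complications.

## Degenerate inputs and tie-breaks

Atom fractions outside [0, 1] are rejected at parse time, never clamped.
Zero tracer fraction, zero volume, zero control rate and empty time
intervals raise typed errors. Fit points are sorted before regression so
permuted inputs give bit-identical coefficients. The carbonate solver
reports unbracketable targets instead of guessing. Mixing with equal
endmembers is a typed degenerate-mixing error.

## Problem sizes

The test suite and the acceptance script use the study-scale designs
directly (six sites, triplicates, 4–5 ΔpH levels, 10⁴–10⁵ Monte-Carlo
draws, a 10⁶-point grid oracle for the carbonate root), which run in
seconds; the 500-repetition coefficient-recovery study uses 15 points per
fit as in the emulated design.
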