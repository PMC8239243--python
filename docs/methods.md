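# Methods

This note documents the models, numerical choices, and limitations behind
each analysis module, and what the synthetic-data generators do and do not
emulate.

## Formula arithmetic

Atomic masses come from a single embedded table of IUPAC 2021 abridged
standard atomic weights (`coordchar.periodic`). Pinning the table makes
two-decimal comparisons against published elemental analyses reproducible
across environments. Hydrate waters are stored separately from the core
composition, and every mass operation takes an explicit basis
(`anhydrous` or `hydrate`): published TGA tables routinely price
water-loss steps on the hydrate mass and the metal-oxide residue on the
anhydrous mass, so a single implicit basis would silently misprice one or
the other.

`fragment_loss_percent` gates, by default, on the fragments' joint element
counts fitting inside the parent. Published step assignments sometimes
fail that gate (fragment lists in the literature frequently do not balance
atomically); the step ledger (`step_mass_balance`) therefore prices such
steps anyway with `strict=False` and records a per-step
`element_balance_ok` flag plus the found−calc residual, rather than
refusing or silently asserting.

Electrolyte classification from molar conductance (≈10⁻³ M in DMF) uses
cut-offs <20 (non-electrolyte), 60–95 (1:1), >120 (2:1) S cm² mol⁻¹;
values between bands are reported as `ambiguous` rather than forced into
the nearer class. The cut-offs are configurable — conductance bands are
solvent-dependent conventions, not constants.

## Titration equilibria

The forward model solves K_f = x/((C_M−x)(C_L−2x)²) for x = [ML₂] by
Brent bracketing on [0, (1−10⁻¹²)·min(C_M, C_L/2)] at 10⁻¹⁴ relative
tolerance; the residual K_f(C_M−x)(C_L−2x)² − x is strictly decreasing on
that interval, so the root is unique. K_f = 0 short-circuits to zero, and
a numerically saturated bracket returns the stoichiometric limit.

`stability_constant` reports two estimates. The pointwise values apply
the mass-action expression at each titration point with x = A/(εb); these
are exact on clean data but amplify noise badly near saturation (the
(C_L−2x) factor vanishes). The headline `kf` is a one-parameter bounded
scalar minimization of the sum of squared absorbance residuals in
log₁₀ K_f over [10⁻², 10¹⁶], which weights all points through the model.
When ε is not supplied it is estimated as max(A)/(b·C_M), i.e. the
saturation plateau is assumed to be fully complexed metal — adequate for
strongly binding systems, biased low otherwise.

The molar-ratio breakpoint fits two least-squares lines with the split
chosen to minimize total squared residual (ties to the earlier split);
the intersection abscissa is the stoichiometric ratio, with [0.28, 0.38]
read as 1:2 and [0.45, 0.55] as 1:1.

The DNA fit regresses [DNA]/(ε_a−ε_f) on [DNA] (ordinary least squares);
K_b = slope/intercept and ε_b = ε_f + 1/slope. The linearization is
algebraically exact for noise-free two-state data, which is what the
round-trip tests exploit. [DNA] is base-pair molarity throughout. An
intercept indistinguishable from zero (unbounded K_b) and mixed signs of
ε_a−ε_f (inconsistent chromism) are hard errors. ΔG = −RT ln K with
R = 8.314 J K⁻¹ mol⁻¹, default T = 298 K.

## Ligand-field and EPR parameters

The d⁷ (Co) and d⁸ (Ni) closed forms are implemented exactly as printed
in the source tables this package is built to reproduce:

* d⁷: Dq = [(85V₃² − 4(V₃−2V₂)²)^½ − 9(V₃−2V₂)]/340, B = (V₃−2V₂+30Dq)/15
* d⁸: Dq = [(9V₂+V₃) − (85(V₂−V₃)² − 4(V₂+V₃)²)^½]/340, B = (V₂+V₃−30Dq)/15

The d⁸ Dq radicand requires |V₂−V₃| ≳ 0.217(V₂+V₃) and is negative for
typical neighbouring band pairs — including the worked Ni case in the
tests. The function then requires a user-supplied 10Dq, uses the linear B
relation, and records in the result that the closed form failed, rather
than guessing an alternative band assignment. Known inconsistency in the
worked Co data: the printed B formula on the printed bands gives ≈742
cm⁻¹, while the source table prints 708; the package reports the
formula's value and the tests document the conflict rather than hiding
it. Wavenumbers convert as 10⁷/λ(nm) and are meaningful to the nearest
cm⁻¹. The covalency threshold on g_av defaults to 2.3 and is
configurable.

## Thermogravimetric kinetics

Segmentation smooths the mass trace with a centered moving average
(default 7 points), computes the DTG rate −dm/dT, and takes maximal runs
above a threshold (default 2% of the peak rate, floor 10⁻⁴ %/K) as
steps. Two refinements matter:

* each step's fit window is expanded into its tails down to 0.5% of that
  step's own peak rate, but never across the rate minimum separating it
  from a neighbour, so overlapping tails stay attributed to their step;
* step mass losses are measured plateau-to-plateau over a contiguous
  partition of the temperature axis cut at those inter-step rate minima,
  so the step losses plus final mass reconstruct the initial mass
  exactly (conservation is a tested invariant).

T_s is defined as the within-step DTG peak temperature.

Both kinetic fits fix reaction order n = 1 (configurable designs exist,
but the classical first-order forms are what this package reproduces)
and restrict to an extent window to avoid the log singularities at
α → 0, 1. Coats–Redfern uses α ∈ [0.05, 0.95] and the conventional
approximation that drops the (1 − 2RT/E_a) factor from the intercept
ln(AR/(β_hE_a)) — under 1% for E_a ≫ RT; on oracle-integrated curves it
recovers E_a to ~0.3%.

Horowitz–Metzger needs more care. The exact slope of ln[−ln(1−α)] versus
T at T_s for a first-order step is E_a/(RT_s²) + 2/T_s; the classical
treatment keeps only the first term, which overstates E_a by 2RT_s —
7–10% at typical decomposition temperatures, i.e. a systematic bias
larger than the method's stated accuracy. This implementation inverts
the full expression, E_a = RT_s(s·T_s − 2) for regression slope s, and
uses a narrower default window α ∈ [0.2, 0.8] because the linearization
around θ = T−T_s = 0 degrades in the tails. A is fixed by the
first-order relation −ln(1−α) = 1 at T = T_s:
A = (β_h E_a/(RT_s²))·exp(E_a/(RT_s)). With these choices HM recovers
E_a to ~3% (median) on oracle curves and agrees with CR within 7%.

Heating rate is accepted in K/min and converted to K/s internally so A
comes out in s⁻¹. Activation thermodynamics use
h = 6.62607015×10⁻³⁴ J s and k_B = 1.380649×10⁻²³ J K⁻¹; the identity
ΔG = ΔH − T_sΔS holds exactly by construction and is asserted.

## Reactivity descriptors

Standard Koopmans-based forms: μ = (E_HOMO+E_LUMO)/2 (negative-midpoint
convention), η = (E_LUMO−E_HOMO)/2, S = 1/2η, ω = μ²/2η. Inverted input
(E_HOMO > E_LUMO) is rejected with a swap hint rather than silently
reordered — published tables occasionally transpose the two values, and
guessing which is which would corrupt μ's sign silently. A degenerate
gap is rejected (infinite softness).

## Cytotoxicity

Survival is 100 × (OD_treated − OD_bg)/(OD_control − OD_bg) with a
per-plate scalar background (mean of the 620 nm background wells). IC₅₀
is linearly interpolated on log₁₀(dose) between the first pair of doses
bracketing 50% survival; an exactly-50% measured dose is returned as-is;
profiles that never cross 50% return a censored result ("> max dose" /
"< min dose") instead of raising; non-monotone profiles warn and use the
first crossing. Four-parameter logistic fitting is deliberately not the
headline method — the interpolation is assumption-light and matches how
screening IC₅₀s are normally quoted. Potency bands have inclusive upper
edges (10 → very strong, 20 → strong, 50 → moderate, 100 → weak).

## Synthetic data

The generators produce the study conditions the estimators are tested
under:

* metal titration: C_M = 3.6×10⁻⁵ M, ligand 1.8×10⁻⁵–1.25×10⁻⁴ M,
  12 points, ε = 10⁴ L mol⁻¹ cm⁻¹, b = 1 cm;
* DNA titration: [DNA] 1.69×10⁻⁶–5.55×10⁻⁶ M (base pairs), 6 points,
  ε_f = 10⁴, ε_b = 5×10³ (hypochromic by default);
* TGA: 10 K/min ramp, 25–800 °C, first-order steps RK4-integrated at
  0.5 K resolution (dα/dT = (A/β_h)e^(−E_a/RT)(1−α));
* MTT: Hill survival 100/(1+(dose/IC₅₀)^h), twofold dilutions
  3.125–400 µg/ml, control OD 1.0, background 0.05.

Noise is additive Gaussian on the measured channel (absorbance, ε_a,
mass %, OD), seeded through `numpy.random.default_rng`; a seed fully
determines the output. TGA noise is off by default so segmentation can
be tested clean and noisy separately. The generators deliberately do not
model instrument physics — baseline drift, stray light, buoyancy, plate
edge effects — so passing round-trip tests demonstrates estimator
correctness under the stated models, not robustness to real-instrument
artefacts. Band-set generation inverts the d⁸ (and d⁷) closed forms so
the linear B relation round-trips exactly.

Problem sizes used by the test suite and acceptance script (12-cell
(E_a, A) TGA grid at 0.5 K resolution, 200-seed Monte-Carlo loops for
breakpoint, K_b-noise and IC₅₀ recovery) were chosen as the smallest
grids on which the medians being tested are stable.

## Known limitations

* Single-wavelength, single-equilibrium titration models only; no global
  multi-wavelength fits, no mixed 1:1/1:2 speciation.
* No Tanabe–Sugano solver: band pairs outside the closed forms' validity
  need an externally supplied 10Dq.
* Kinetics are model-fitting (first-order CR/HM), not isoconversional;
  activation parameters inherit the usual compensation-effect caveats.
* The ε-from-plateau estimate assumes full complexation at the highest
  ligand ratio.
* IC₅₀ interpolation needs a 50% crossing inside the dose range;
  censored results carry no confidence interval.
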