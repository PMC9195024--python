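# Methods

`radequiv` characterizes the radiological water-equivalence of phantom
and bolus materials — in particular generic polydimethylsiloxane
silicone (C2H6OSi) against Gammex/RMI-457 solid water and water — from
elemental compositions alone, and emulates slab-interface dose-ratio
measurements with a photon Monte Carlo. This note records the models,
their assumptions, the numerical choices, and the known limits of what
the package (and its passing tests) can claim.

## Stoichiometric quantities

Every derived quantity starts from a `MaterialComposition`: a mass
fraction vector w_i over elements plus a bulk density ρ (g/cm³).
Compositions must sum to 1 within 0.002 — a tolerance chosen so that
published compositions whose printed fractions sum to 0.999 are accepted
verbatim; an explicit renormalize flag rescales anything further off.

* **Electron densities.** electrons/g = N_A Σ w_i Z_i/A_i;
  electrons/cm³ multiplies by ρ; RED is the electrons/cm³ ratio to a
  reference (water by default). RED drives megavoltage photon
  attenuation because the Compton cross-section per unit volume is
  proportional to electron density.
* **Effective atomic number.** Mayneord's power law
  Z_eff = (Σ a_i Z_i^m)^(1/m) with m = 2.94. The classic form weights by
  fractional electron content a_i ∝ w_i Z_i/A_i (the default); a
  mass-fraction variant is exposed behind a flag because published
  tabulations are inconsistent about the convention — for silicone the
  two give 10.37 (electron) and 10.65 (mass), and tabulated values for
  silicon-rich media typically match the mass-fraction form while
  water/solid-water values match the electron-fraction form. The package
  computes either and never silently picks between them.
* **Mean excitation energy.** Bragg additivity on ln I with
  ICRU-37/ESTAR compound-adjusted elemental constants (H 19.2, C 81,
  N 82, O 106 eV; I_adj = 1.13 I_elem for Z > 8). Water is special-cased
  to the recommended 75.0 eV via a per-material override (plain
  additivity with these constants gives 75.3 eV); the same override
  mechanism is available to any user material with a measured I.

## Photon interaction coefficients

The bundled `analytic` mode builds compound coefficients from:

* **Incoherent:** closed-form Klein–Nishina total and energy-transfer
  cross-sections per free electron, scaled by electrons per gram.
  Electron binding is neglected, which is accurate above ~100 keV in
  low-Z media and exact in ratios between media of similar composition.
* **Photoelectric:** Born-approximation Sauter-type Z⁵α⁴ scaling with an
  ε^(-7/2) → ε^(-1) roll-over (ε = E/m_ec²).
* **Pair:** Born cubic-threshold law near 2m_ec², unscreened
  Bethe–Heitler form at high energy, per-atom Z².
* **Rayleigh: omitted.** It transfers no energy, contributes ≲1% to
  attenuation above 100 keV, and nearly cancels in material ratios.

Mixture additivity is exact by construction (every compound column is
the mass-weighted sum of pure-element columns), and the test suite
asserts it to machine precision. μ_en/ρ applies a radiative-loss factor
g, modeled as zero below 2 MeV and a Z-scaled linear ramp
(3.5·10⁻⁴ ⟨Z⟩ (E−2) per MeV) above — consistent with g ≈ 0.015–0.02 for
water at 10 MeV and well below 1% at the Co-60/6 MV energies this
package targets. Note the ramp uses the compound's mean Z, so strict
additivity of μ_en/ρ holds only below 2 MeV.

Coefficients are evaluable on [0.01, 10] MeV so that the Monte Carlo can
transport degraded scatter down to its 10 keV cutoff; accuracy
statements (e.g. water μ/ρ at 1.25 MeV within 2% of the published
0.0632 cm²/g) apply above 0.05 MeV. Below ~50 keV the photoelectric fit
is only good to tens of percent and the package makes no kilovoltage
claims.

Spectrum-averaged ratios weight the per-energy coefficient by the
photon fluence times energy (energy-fluence weighting, the default) or
by fluence alone; for Co-60 the two differ by < 0.3% and a test pins
that bound.

## Stopping powers and spectrum-averaged ratios

Unrestricted mass collision stopping powers use the ICRU-37 Møller
closed form with k = 0.1535 MeV·cm²/g and m_ec² = 0.511 MeV; the
restricted form L_Δ replaces F⁻(τ) with the standard G⁻(τ, η = Δ/T) and
reduces to S_col exactly at Δ = T/2 (asserted to machine precision).
The density-effect correction δ uses Sternheimer's 1971 general recipe
computed from (ρ, Z/A, I) rather than per-material fitted parameters,
so arbitrary synthetic compounds are supported; for water this recipe
gives δ(1 MeV) = 0.211 vs the exactly-fitted 0.243 — a ~13% error in δ
that translates to < 0.2% in S_col at 1 MeV and largely cancels in
ratios between similar media. Supported kinetic-energy range:
0.01–50 MeV.

Mean stopping-power ratios average L_Δ over the Compton-generated
slowing-down electron fluence in the *reference* medium
(ratio-of-doses convention): the initial recoil spectrum is the
Klein–Nishina cross-section differential in recoil energy summed over
spectral lines, and the continuous-slowing-down fluence is
Φ(T) ∝ N(T′ > T)/S_col(T). δ-ray buildup, bremsstrahlung losses, and
pair/photoelectron sources are neglected; a first-order Møller
knock-on iteration was evaluated during design and moves the Co-60
silicone/water ratio by < 0.1%, so the simpler spectrum is shipped.
Integration uses a 400-point log grid from Δ (or 10 keV when
unrestricted) to the highest Compton edge, trapezoidal rule; the grid
is converged to ~10⁻⁴ relative.

**Known discrepancy.** For silicone/water at Co-60 with Δ = 10 keV this
machinery yields 0.9415, while the published characterization prints
0.930. The pointwise restricted ratio runs from 0.928 at 10 keV to
~0.95 at 1 MeV, and a spectrum average is bounded by those extremes
(the mean-value property, also asserted by a test); reaching 0.930
would require essentially all fluence weight below ~30 keV, which no
physical Co-60 secondary-electron spectrum provides. δ-ray buildup and
Spencer–Attix track-end terms (both evaluated) shift the average by
≲ 0.2%. The same publication's solid-water restricted-ratio entries
(1.067/1.080) are inconsistent with any stopping-power data we can
construct, so the printed restricted-ratio row appears unreliable; the
package reports its own computed values. The unrestricted silicone/water
ratio for a 6 MV-like spectrum computes to 0.951, consistent with the
independently published 0.948 within 0.4%.

## Slab-geometry photon Monte Carlo

Analog transport of photons from a point source through a stack of
homogeneous slabs: divergent square field (10×10 cm² at 100 cm SAD in
the reference setups), free paths from layerwise total attenuation,
interactions sampled among incoherent (Klein–Nishina on free electrons,
scattered fraction by rejection sampling), photoelectric (local
absorption), and pair production (local absorption of E − 1.022 MeV plus
two isotropic back-to-back 0.511 MeV photons). Photons below 10 keV are
absorbed on the spot — their range in these media is far below the
0.1 cm bin width. No variance reduction is applied to transport.

**Scoring.** Collision kerma in 0.1 cm depth bins over a centered
1×1 cm² column, as energy per unit mass per history (MeV/g). Two
tallies:

* `track_length` (default): an expected-value estimator — every flight
  segment crossing the scoring column deposits
  E·(μ_tr/ρ)·(path length)/V_bin. Transport remains analog; only the
  tally takes the expectation, which is what makes sub-percent ratio
  statistics reachable at 10⁷-history scale on one CPU (a pure
  collision tally collects only ~50 scoring events per 10⁶ histories in
  a 0.1 cm × 1 cm² voxel and would need ~10⁹ histories for the same
  precision).
* `collision`: the sampled energy transferred to electrons is deposited
  at each interaction point. Kept for validation; a test asserts the two
  tallies agree within statistics.

Statistics are history-by-history over 10 equal batches (per-bin batch
standard error; a test pins the 1/√N scaling), and runs are bitwise
reproducible for a given (seed, histories, batches). Layer boundaries
must align with bin edges so each bin has a unique medium; the
"interface dose" convention is the last bin of the upper slab (the film
position between slabs), with the lower-side bin equally accessible.

**What collision kerma does and does not reproduce.** Electrons are not
transported, so dose equals collision kerma only under charged-particle
equilibrium. Homogeneous-phantom ratios at depth (e.g. full silicone vs
full solid water at 5 cm, which computes to 1.003 ± 0.003 against the
published full-transport value 1.001 ± 0.004) are reproduced. The
sub-millimetre electron-fluence perturbation at a silicone/solid-water
interface is *not*: full-transport interface ratios sit ~2% below unity
(silicone releases ~2% less energy per unit volume, and the interface
dose inherits that deficit over the electron range ~2–4 mm), while a
photon-kerma model predicts ≈ +0.2% (silicone's lower per-cm attenuation
slightly *raises* the interface fluence). The package's interface-ratio
direction check is therefore expected to fail and is documented as such;
treat mixed-media interface ratios from this model as photon-fluence
statements only.

## Uncertainty budgets and measured ratios

Budgets are flat lists of (label, percent, type A/B) combined in plain
quadrature regardless of type, scaled by the coverage factor k
(GUM-style, all components treated as uncorrelated and relative). The
bundled chamber budget combines to 0.92% (k=1) / 1.84% (k=2), matching
its published table exactly after 2-decimal rounding; the film budgets
combine to 2.0518% (Co-60) and 1.0941% (linac) where the source table
prints 2.06 and 1.11 — a 0.01–0.02 discrepancy in the source's own
arithmetic that is recorded, not chased. Measured ratios are ratios of
reading-set means; each side's combined relative uncertainty is the
quadrature of its budget and (for n > 1) the standard error of its mean,
and the ratio uncertainty is the quadrature of the two sides. No
correlated-uncertainty modeling: shared components (e.g. the same
calibration factor in numerator and denominator) are *not* cancelled,
which makes the reported u conservative and matches how the reference
tables were constructed.

## Synthetic data

The generator module supplies every input with known ground truth:
Dirichlet(1) mass fractions over a chosen element pool with uniform
density (always valid by construction); Gaussian reading sets whose
relative standard deviation equals a budget's combined k=1 percent
(non-positive draws rejected); and an analytic depth-dose stand-in —
exponential line-by-line attenuation × local μ_en/ρ × inverse square ×
a 1 − exp(−d/0.3 cm) buildup ramp — with a closed-form ratio for any
two configurations. The buildup constant is Co-60-like and cancels
exactly in same-depth ratios, so its precise value is immaterial.
The synthetic 6 MV spectrum is thin-target bremsstrahlung
(E_max − E)/E hardened by 25 cm of water-equivalent filtration, chosen
so the mean energy (1.80 MeV) matches documented clinical 6 MV beam
quality; it is a stand-in, not a measured linac spectrum, and every
6 MV-conditional number inherits that caveat. What the generators do
not emulate: film-specific spatial noise, detector perturbation
effects, CT/HU calibration chains, and electron-beam transport.

## Problem sizes used by the shipped checks

Deterministic quantities are exact-arithmetic scale (instantaneous).
The stopping-ratio averages use 400-point log grids. Monte Carlo
checks use 10⁷ histories per configuration in the test suite and
4×10⁷ in the reproduction script (ratio standard error ≈ 0.3–0.5%),
sizes chosen as the point where statistical error is comfortably below
the tolerances being tested.
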