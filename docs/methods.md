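# Methods

This note documents the models, conventions and numerical choices behind
each reduction, what the synthetic-data generators emulate, and the known
limitations — in particular which outputs are quantitative and which are
qualitative by construction.

## Particle-size statistics

Laser-diffraction instruments report volume-weighted quantiles. Span is
computed directly from the (mean) quantile triple. When a parametric form
is needed, a lognormal volume distribution is fitted with median = D50 and
ln(GSD) as the average of the two symmetric quantile estimates
ln(D90/D50)/z₀.₉ and ln(D50/D10)/z₀.₉; three quantiles over-determine the
two parameters, so printed triples that are not exactly lognormal yield a
compromise fit, and the Span recomputed from the fit can differ slightly
from the Span of the raw triple. Replicate-level Span averaging is
supported but the default works on mean quantiles; published tables that
averaged per-replicate Spans will differ in the last digit, which is why
worked-value checks on Span use a ±0.01 band.

SSA assumes spheres: SSA = 6/(ρ·D32) with the Sauter mean of the
volume-lognormal D32 = D50·exp(−½ln²GSD) (Hatch–Choate; the closed form is
verified against quadrature of the volume density in the tests to 0.1%).
Instrument SSA values come from the full measured distribution and an
internal shape model, so agreement with them is qualitative (order of
magnitude and ranking), not numeric.

## Flowability

Hausner ratio and Carr index are exact arithmetic; the two are linked by
HR = 1/(1 − CI/100), which the tests assert as an identity. Replicates are
reduced ratios-first (per-replicate HR/CI, then mean) by default because
that is what replicate-averaged published tables correspond to;
densities-first is available. The flow-character labels follow the USP
⟨1174⟩ scale with boundary values assigned to the better class. Published
tables occasionally label CI values in the 26–31 band "very poor"; the
package reports the scale's own label ("poor") and logs the difference in
the study pipeline rather than replicating it.

## Wu surface energetics

The two-liquid Wu harmonic-mean system is solved with scipy's hybrid
Powell root finder multi-started from a 4×4 grid over [5, 95]² mN/m;
solutions are accepted when both residuals are below 1e−8 mN/m, clipped to
[0, 200]², and if distinct roots survive deduplication the smallest-residual
one is returned with a warning. Probe-liquid components default to the
literature values for water (γd = 22.6, γp = 50.2 mN/m) and diiodomethane
(γd = 49, γp = 1.8 mN/m) and are overridable. Angles are degrees at the
interface; trig is internal radians.

Because raw contact angles are rarely published, verification is by
construction: a forward model computes the angles a given (γs^d, γs^p)
predicts, and the solver must invert them to 1e−6 mN/m. Not every
component pair is invertible — sufficiently high-energy solids completely
wet a probe liquid (predicted cos θ > 1), so no finite contact angle
exists; the forward model raises in that region and round-trip checks
sample only admissible pairs. Time-resolved angle relaxation over the
detection window is out of scope; a single angle per pastille is assumed.

## XRPD crystallinity

Characteristic drug reflections (defaults at 6.6, 11.4, 13.1, 13.5, 15.1,
18.7, 19.3, 25.9, 26.4° 2θ; leucine peaks excluded) are integrated by the
trapezoid rule above a local linear baseline drawn between the edges of a
±0.25° window, clipped at zero. Crystallinity is the ratio of summed peak
areas, sample over physical-mixture reference, ×100; the per-peak mean of
ratios is available because the summary wording of such analyses is
ambiguous — the two coincide exactly under uniform amplitude scaling.
Equal drug loading in sample and reference is assumed; no Rietveld or
profile fitting. Flat baseline offsets cancel exactly; sloped or curved
backgrounds cancel only approximately within the narrow windows.

## Dissolution and permeation

The withdrawal correction assumes each withdrawn aliquot (Vs out of V) is
replaced by fresh medium instantly and mixing is ideal, giving
C*ₙ = Cₙ + (Vs/V)·Σᵢ<ₙ Cᵢ and released % = C*ₙ·V/dose·100. Protocol
defaults: V = 50 mL, Vs = 5 mL, dose = 1.5 mg, sampling at 5/10/15/30/60
min — all overridable. Flux is the cumulative permeated mass over membrane
area (0.785 cm²) and duration; Kp = J/Cd with Cd defaulting to
dose/donor-volume = 1500 µg/9 mL ≈ 166.7 µg/cm³. That default reproduces
published Kp values for formulations that fully disperse in the donor; a
raw, solubility-limited drug has an unknown effective Cd and the pipeline
flags such rows instead of guessing.

## Cascade impactor reduction

Stage cut-offs are the standard eight-stage values at 28.3 L/min
(9.0, 5.8, 4.7, 3.3, 2.1, 1.1, 0.7, 0.4 µm + terminal filter); a Q^(−1/2)
rescaling helper exists but is off by default. Conventions, chosen once:

* ED includes the induction port (drug "reaching the impactor"), so EF can
  be high while a sizeable fraction never reaches a calibrated stage.
* The induction port is excluded from the sizing regression — it has no
  calibrated cut-off. Stage 0 has no upper size bound.
* The cumulative-undersize fraction at a stage's cut-off is the sized mass
  on strictly deeper stages over total sized mass; points exactly 0 or 1
  are dropped (probit undefined); at least two interior points required.
* MMAD = 10^(−a/b) and GSD = 10^(1/b) from the least-squares probit line
  probit(F) = a + b·log₁₀(d); a non-positive slope raises.
* FPD evaluates the fitted lognormal CDF at exactly 5.0 µm (interpolation
  on the regression line, not stage truncation at 4.7 µm) times the sized
  mass; FPF = FPD/ED·100.

Noise-free lognormal stage data are exactly collinear on the probit scale,
so recovery is limited only by floating point; the 2% recovery band in the
tests covers discretization at extreme MMADs near the stack edges.

## Stochastic lung deposition

The simulator implements the classical stochastic airway Monte Carlo
family: empirical extrathoracic filter → random walk down a randomized
branching tree with analytic per-segment deposition probabilities. Its
regional outputs are intended for qualitative ordering (breath-hold,
particle-size and flow effects) and internal-consistency studies; the
absolute percentages depend on the morphometry table and empirical
coefficients shipped here and are not calibrated to reproduce any specific
published deposition table.

**Geometry.** 24 generation classes (16 bronchial, 8 acinar) with median
diameters and lengths from a Weibel-type symmetric-average adult
morphometry, isotropically rescaled so the cumulative tree volume equals a
functional residual capacity of 3300 cm³ (this lumps alveolar volume into
the duct volumes for penetration bookkeeping; individual-airway databases
are not redistributed). Randomization: per-generation lognormal
diameter/length (geometric SD 1.10–1.15), uniform branching and gravity
angles in tabulated ranges. Flow splits dichotomously (Q/2^(g−1)).

**Per-segment physics** (CGS, 37 °C: μ = 1.90e−4 P, λ = 0.0712 µm):
impaction uses the Yeh–Schum bifurcation form in θ·Stk; flowing
sedimentation the Yeh–Schum exponential form with exponent
(8/π)·v_ts·t·cosφ/D; flowing diffusion the Gormley–Kennedy laminar-tube
solution in μ = D_B·L/Q with the small-μ branch below 0.009. Breath-hold
uses quiescent forms: settling with exponent (4/π)·v_ts·t·cosφ/D and the
first cylindrical Fourier mode exp(−5.784·D_B·t/R²) for diffusion.
Mechanisms combine as P = 1 − Π(1 − Pᵢ). The extrathoracic filter is a
Rudolf-type sigmoid in the impaction parameter d²Q, P = 1 − 1/(a·x^b + 1),
oral (a = 1.1e−4, b = 1.4) by default; nasal coefficients are shipped but
untested.

**Manoeuvre.** Default breathing: 1.7 L inhaled over 3.2 s (a COPD patient
through a capsule inhaler), breath-hold 5 s, exhalation time equal to
inhalation time (not separately specified in typical protocols;
configurable), oral mode. A particle enters at a uniform random time
fraction of the inhalation, penetrates as deep as the remaining inhalable
volume allows against the cumulative median tree volume, holds in the
airway reached, and retraces its path on exhalation. Particles are unit
density spheres when specified by aerodynamic diameter.

**Randomness.** One seeded NumPy Generator per simulation with a fixed,
documented draw order (sizes → extrathoracic → geometry → inhalation →
breath-hold → exhalation uniforms). Runs differing only in breath-hold
time therefore share all random numbers, making breath-hold monotonicity
exact per particle, not just in expectation. Regional tallies are integer
counts, so the four fractions sum to 100% to machine precision; standard
errors are binomial.

**Problem sizes.** Default 10⁴ particles (regional SE ≈ 0.5%); the
analytic single-tube cross-check runs 10⁵ particles against the closed
form within three binomial standard errors. The test suite uses 2×10⁴ for
ordering checks.

## Synthetic data

Every generator is the forward model of exactly one reduction: quantiles
from a lognormal, density replicates from target HR/CI, contact angles
from known surface-energy components, Gaussian-peak diffractograms at a
known crystallinity, first-order dissolution sampled through the actual
withdrawal protocol (so the correction is exercised, not bypassed), and
impactor stage masses from a lognormal APSD partitioned by the stage
cut-offs. Noiseless round trips therefore close to solver tolerance, and
noise (multiplicative lognormal or additive Gaussian per kind, SDs
defaulting to the order of published replicate SDs) degrades recovery
monotonically. What this does *not* show: real powders deviate from
lognormality, real diffractograms have structured backgrounds and
preferred orientation, real impactor runs have inter-stage wall losses —
passing round trips validate the inverse machinery, not these physical
effects.

## Known limitations

* SSA and the lung simulator are order-of-magnitude/ordering tools, not
  calibrated predictors (see above).
* No Mie inversion, DSC deconvolution, Noyes–Whitney fitting, NGI
  geometry, hygroscopic growth or mucociliary clearance.
* The Owens–Wendt geometric-mean surface-energy variant is not
  implemented; only the Wu harmonic-mean model is used.
* The API-content assay is a pass-through input to the impactor report,
  not modelled.
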