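# Methods

This note documents the models, numerical choices and limitations behind
`saxskit`. Momentum transfer is defined throughout as `s = 4π sin(θ)/λ`
(2θ the scattering angle), internally always in Å⁻¹; nm⁻¹ input is converted
on read (exact factor of 10).

## Scattering from coordinates

Intensities are computed with the Debye formula,

    I(s) = Σⱼ Σₖ Re[f_j f_k*] · sin(s·r_jk)/(s·r_jk),

which is exact for a set of point scatterers and needs no truncation-order
choices; the cost is O(N²·|s-grid|), acceptable for desk-scale models
(≤ ~5000 atoms). Occupancies multiply form factors linearly. The calculation
is vacuum scattering: no hydration shell and no excluded-volume solvent term
are modelled — calculated curves are comparable to each other and to
simulated data derived from them, not directly to solvent-subtracted
experimental curves.

Form factors are `f(s, E) = f0(s) + f′(E) + i·f″(E)`. The wavelength-
independent part f0 uses the Cromer–Mann sum-of-Gaussians coefficients
embedded in gemmi (International Tables vol. C); `f0(0) = Z` within 0.1 e is
asserted for every supported element, and an independently transcribed
Waasmaier–Kirfel row for oxygen serves as a cross-tabulation check in the
tests. Anomalous corrections come either from user ASCII tables
(`energy_eV f′ f″`, linearly interpolated — tables are dense near edges and
higher-order schemes risk edge overshoot) or, built in, from gemmi's
Cromer–Liberman implementation, restricted to elements Ca–U and energies
1.0–29.4 keV. Theoretical corrections ignore the chemical environment of the
absorber; user tables exist precisely to override them. In anomalous mode the
full complex modulus is kept, i.e. the f′/f″ cross terms are included in
|f|²; with an all-zero correction table the result is bit-identical to the
regular mode.

Absolute scale (`.abs`) multiplies an electrons² curve by
`r_e²·N_A/MW·10⁻³` (classical electron radius r_e² = 7.9407×10⁻²⁶ cm²,
Avogadro N_A = 6.02214076×10²³ mol⁻¹), yielding cm⁻¹ per mg/ml with an
implicit 1 cm beam path.

## Detector image simulation

The simulator is purely statistical. Expected counts per pixel are

    μ_ij = I_abs(s_ij) · c · Φ · t · T · η · ΔΩ_ij,

with concentration c, flux Φ, exposure t, transmission T, detector
efficiency η, and the flat-detector solid angle
`ΔΩ = (pixel²/D²)·cos³ψ` (point sample, ψ the off-normal angle). Observed
counts are independent Poisson draws from a single seeded generator;
replicate frames use distinct seeds. Systematic instrument effects —
polarization, point-spread, dead time, self-absorption, smearing — are
deliberately outside the model: the design goal is that *reduced* simulated
data carry the same statistical properties as measured data (reduced χ² ≈ 1
round trips), not bit-level compatibility with any particular instrument.
The exact per-pixel expectation formula is this package's own documented
reconstruction and is validated through those statistical properties.

Simulated images carry an optional per-pixel normalisation grid
(`photon_factor·ΔΩ`, the expected counts per unit absolute intensity) so
that reduction can return curves in the source units.

## Radial averaging

Each unmasked pixel belongs to exactly one equal-width s-bin between the
smallest and largest s of unmasked pixels (no pixel splitting, keeping ring
estimates statistically independent; the bin count is the user's resolution
choice). Within a ring, Poisson counts are variance-stabilized with the
Anscombe transform `y = 2√(x + 3/8)` and outliers rejected where the
median-based robust z score `0.6745·(y − med)/MAD` exceeds 4 (two-sided by
default, one-sided available; MAD = 0 keeps everything). The ring intensity
is the ratio estimator `Σx / Σk` over kept pixels (k the normalisation, 1
when absent), with Poisson error `√(Σx)/Σk`; a zero-count ring receives the
one-count error bound. The bin's s coordinate is the plain mean s of kept
pixels — intensity-independent, so noise cannot bias the abscissa. With
rejection disabled, averaging N reduced curves and reducing the N-frame sum
agree exactly (identically in I and σ), which the tests assert.

## Curve comparison statistics

Three tests of "identical up to noise", sharing the standardized residuals
`r_i = (I1_i − I2_i)/√(σ1² + σ2²)`:

* **Reduced χ²** — `χ²_red = (1/n)Σ r_i²`, p from the upper tail of χ² with
  ν = n (nothing is fitted in a pure two-curve comparison). Requires
  well-estimated errors.
* **Correlation map** — the longest run C of consecutive same-sign
  differences; p is the exact probability that the longest run of identical
  outcomes in n fair Bernoulli trials reaches C, via the classical recursion
  for head-run counts (a run of C identical outcomes among n trials is a run
  of C−1 successes among the n−1 "same as previous" indicators). Exactness
  is verified against brute-force enumeration of all 2ⁿ sign sequences at
  small n. Zero differences count as positive — ties are measure-zero on
  real data. Error estimates are not used at all.
* **Anderson–Darling** — case-0 A² of the residuals against the fully
  specified standard normal, p from the Marsaglia & Marsaglia asymptotic
  evaluation; for A² > 12 the series underflows and p is reported as 0.
  The asymptotic p is unreliable below n ≈ 8 (warned).

For calibrated data ≈99% (theoretically 99.73%) of standardized residuals
fall within ±3; the suite checks ≥ 99% at n = 2500 and that each test's
type-I error sits at ~1% for α = 0.01 over 1000 Poisson-replicate trials
(CorMap's attainable level is at or below the nominal one because its null
is discrete).

Parametric resampling draws `I* ~ Normal(I, (scale·σ)²)` per point with σ
carried over unchanged. The width multiplier defaults to 1.0 and is exposed
because the appropriate inflation for "additional uncertainty" is
data-dependent; the resampling-based validation of the Guinier-fit standard
error is exercised in the tests.

## Real-space transforms

The transform pair

    I(s) = 4π ∫₀^Dmax p(r)·sinc(sr) dr        (forward)
    p(r) = (r/2π²) ∫₀^∞ s·I(s)·sin(sr) ds     (inverse)

is evaluated by trapezoid quadrature. The inverse integral runs over three
segments: `[0, s_min]` with the Guinier model `I0·exp(−s²Rg²/3)` (Rg and I0
are required inputs), the measured range on the data grid (no resampling —
best results on low-noise, equidistant grids), and `(s_max, s_cut]` with a
power-law tail `A·s⁻ⁿ` (n = 4 for globular particles, 2 for flexible
chains). The tail amplitude is fitted by linear least squares of I against
s⁻ⁿ over the top 10% of the s-range (fraction configurable); fitting linearly
in A rather than in log-log space keeps the fit defined when noisy or
oscillating intensities cross zero. The tail is integrated numerically to
`s_cut = 10·s_max` by default (30·s_max in the stringent tests), with a
convergence warning if the outer half of the cutoff interval still
contributes more than 10⁻⁴ of the result. p(0) = 0 exactly (the r prefactor)
and p(D_max) is pinned to 0, D_max being the asserted support.

Derived moments: `I(0) = 4π∫p dr`, `Rg² = ∫r²p dr / 2∫p dr`, and the peak
position. On truncated solid-sphere data the recovered p(r) agrees with the
closed-form distance distribution within 2% RMS of its peak and the moment
Rg within 1%.

Termination-effect suppression is demonstrated on the exponential-
correlation pair `p(r) ∝ r²e^(−r/a) ⟷ I(s) ∝ (1+s²a²)⁻²`, whose high-angle
tail is asymptotically *exactly* `A·s⁻⁴`: there the continuation shrinks
near-D_max artifacts by well over 5×. The solid sphere is deliberately not
used for this property: its tail oscillates through zeros, so the error near
D_max is dominated by the unrepresentable oscillating component rather than
by the truncation step, and no smooth power-law continuation (amplitude-
fitted or endpoint-anchored — both were measured) changes it materially.

## Model-free invariants

The Guinier fit is a weighted linear regression of ln I on s² over the
largest low-s window with `s·Rg ≤ srg_limit` (default 1.3), found
self-consistently starting from the half-height window (far more noise-
robust than the first few points). Weights are `(I/σ)²` — the linearization
of σ-weighted least squares on I — and, when σ is absent, `I²`, the
linearization of *unweighted* least squares on I; this keeps the two cases
consistent and concentrates the fit where the Guinier model holds best.
Standard errors come from the weighted regression (delta method for Rg).
Note the approximation itself is biased on compact shapes: for an ideal
sphere the fitted Rg exceeds √(3/5)·R by ~1% at `s·Rg ≤ 1` and ~1.6% at 1.3;
the 1%-level recovery asserted in the tests therefore uses the `s·Rg ≤ 1`
window.

Porod invariant `Q_p = ∫s²I ds` and volume `V_p = 2π²·I0/Q_p`; volume of
correlation `V_c = I0/∫sI ds`. Both integrals are continued beyond s_max
with the fitted `A·s⁻⁴` tail (analytically: `A/s_max` and `A/(2s_max²)`);
if the amplitude fit fails the continuation is skipped with a warning. All
invariants are strictly scale-invariant in I. MW estimates:
`MW_vp = V_p·10⁻²⁴/(v̄·1.66054×10⁻²⁴)` Da with partial specific volume
v̄ = 0.74 cm³/g by default (no shape-correction factors are applied, so
V_p-based masses carry the usual few-10% systematic), and the
volume-of-correlation power law `QR = V_c²/Rg`, `MW = (QR/0.1231)` for
proteins and `(QR/0.00934)^0.808` for RNA (constants from the Rambo–Tainer
survey, selectable via `kind=`). No Bayesian consensus of estimators is
attempted; the report carries the individual estimates.

## Synthetic fixtures

All oracles are closed-form: the solid-sphere curve
`I/I0 = [3(sin x − x cos x)/x³]²` (x = sR, first zero at x ≈ 4.4934, Guinier
radius √(3/5)·R), its distance distribution `r²(1 − 3u/4 + u³/16)` on
[0, 2R] (u = r/R), the thin-shell and two-point curves, uniform point clouds
in a ball (inverse-CDF radial sampling), and Gaussian noise with the
recorded sigma model `σ = noise·(|I| + 0.01·max|I|)` (proportional noise
with a floor so σ stays positive through intensity zeros). Gaussian noise
emulates *reduced* 1D data well (ring estimates are sums of many counts) but
not raw low-count pixels; pixel-level behaviour is always exercised through
the Poisson image simulator instead.

## Problem sizes and determinism

The test-suite defaults — 740² detector pixels at ~2500 rings, 2000-point
Debye clouds, 100 simulation round trips, 1000 calibration trials — were
chosen as the smallest sizes at which the asserted statistical tolerances
(3σ binomial or sampling bands) are meaningful. Every stochastic step takes
an explicit integer seed; identical seeds and inputs reproduce results
bit-for-bit.

## Known limitations

* Vacuum scattering only; no hydration shell, excluded volume, or fitting to
  experimental data.
* Neutron (SANS) smearing, incoherent backgrounds and resolution functions
  are not modelled.
* mmCIF handling covers the atom_site category (first model, altloc A/blank);
  chain/residue semantics beyond element + coordinates are out of scope.
  Atom serials past 99999 are renumbered modulo 99999 on PDB export.
* The direct Fourier transform requires trustworthy Rg/I0 inputs and clean
  low-angle data (no aggregation/interparticle interference); it is a
  cross-validation tool, not a replacement for regularized indirect
  transforms.
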