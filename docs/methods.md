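# Methods

This note records the models implemented in `dnamech`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions a user should know before trusting a
number.

## Resonator model

The bundle is an Euler-Bernoulli doubly clamped beam. Modal factors λ_n are
computed at run time by bracketed Brent root-finding on the characteristic
equation, rewritten as cos λ − sech λ = 0 so that high modes do not overflow
cosh; root *k* is bracketed in (kπ, (k+1)π) and solved to ~1e-12. Textbook
eigenvalue constants appear only in tests, as independent cross-checks.

Three frequency forms are provided and are algebraically equivalent for a
circular section: the general area/second-moment form, the radius form, and
the unstressed special case. Their mutual agreement to 1e-12 relative is a
tested invariant, not an assumption.

**String limit.** When tension dominates, the implemented prefactor is the
standard taut string f_n = n/(2L)·√(σ/ρ), with integer modal factors. This
is the form the tension-dominated limit of the general beam expression
reproduces (up to the λ_n → nπ replacement of the boundary-condition
eigenvalues); a commonly quoted variant with a λπ/L prefactor differs by a
constant factor that cancels in every mode ratio, and mode ratios are the
only string-limit quantity the inference chain uses. The
`high_tension_limit_check` operation makes the limit testable: it reports
the dimensionless tension term and the ratio of the beam frequencies to
λ_n/(2πL)·√(σ/ρ).

**Elliptical splitting.** The two orthogonal flexural planes see the two
principal second moments of the elliptical section. We use the standard
ellipse results in semi-axis form, I_major = πa³b/4 with a = d_max/2 (i.e.
π·d_max³·d_min/64) and area A = π·d_max·d_min/4, so that the degenerate
ellipse d_max = d_min reproduces the circular beam frequency exactly — a
tested invariant — and f_fast/f_slow = d_max/d_min holds to machine
precision (the slow mode is derived from the fast one through that exact
ratio to avoid spurious one-ulp ordering violations at zero eccentricity).
Splitting is modelled on the unstressed beam; supplying a stressed material
is rejected rather than silently ignored.

**Asymmetry conventions.** The diameter-space asymmetry
Ω = (d_max−d_min)/d_min and the frequency-space estimate (f_f−f_s)/f_f are
equal only to first order: the frequency form equals (d_max−d_min)/d_max
exactly. `asymmetry_from_split` reports both the frequency-space Ω and the
exact diameter ratio f_f/f_s; `diameter_difference_from_omega` uses the
diameter-space definition Ω·d_min. For Ω ≈ 1% the conventions differ by
~1%, relative, of Ω itself; tests pin the discrepancy at ≤ 2Ω² relative up
to Ω = 5%.

**Tension.** Effective-modulus extraction assumes σ = 0, following the
modal-ratio evidence that the suspension process leaves the bundles
essentially unstressed; σ remains an explicit model parameter everywhere so
the approximation is testable (and the classifier flags tension-dominated
inputs as strings).

**Mass sensing.** S = −f/2m (reported as |S| in Hz/ag at presentation
boundaries) and Δm_min = 2m·(δf/f). The fractional frequency stability δf/f
is a required user input, not a default: it is an instrument property that
cannot be derived from geometry. All internal computation is SI; ag, GPa
and Hz/ag conversions live in `units.py` and are applied only for display.

## Spectra

The lineshape is the driven damped harmonic-oscillator amplitude
a·f₀²/√((f₀²−f²)² + (f₀f/Q)²) — the standard response of a piezo-driven
resonator read out by vibrometry. Its half-power bandwidth approaches f₀/Q
for large Q, which makes the "resonance frequency over 3 dB bandwidth"
definition of Q exact in that limit. The crossing level is the half-power
point, amplitude factor 1/√2 of the peak; reading "3 dB" strictly on an
amplitude-decibel scale (factor 10^(−3/20) ≈ 0.708) would change the
bandwidth by ~0.1%, and a half-*amplitude* convention would widen it by √3
— the half-power convention is the one that reproduces Q = f₀/BW for this
lineshape. The estimator is tested to agree with the fitted Q within 5%
down to Q = 5 (low-Q lineshape asymmetry accounts for the residual bias).

Peak detection Savitzky-Golay-smooths the trace (window ≤ 15 samples,
quadratic) and applies a prominence floor of max(10× the post-smoothing
noise scale, 5% of the smoothed dynamic range); an exactly flat trace
returns no candidates. Fitting is nonlinear least squares (lmfit) of one
oscillator plus a constant background over a window of ±5 estimated
bandwidths (±2 in the multi-mode pipeline, to keep neighbouring air modes
out). Q is bounded above by f₀/(3·grid step): a peak narrower than a few
samples is not credible on any grid that satisfies the ≥50-points-per-
bandwidth sampling contract. Non-convergence, or failure to beat a constant
model, raises a diagnostic error — never a silent garbage fit.

Doublet resolution fits one- and two-oscillator models and declares the
doublet resolved only when the two-peak fit improves AIC by ≥ 10 and the
centers are separated by more than one grid step; ties fall back to the
single peak with an explicit unresolved flag. This reproduces the
separation/bandwidth resolvability criterion Ω·Q ≳ 1: vacuum doublets
(Ω·Q ≈ 2.9 at the default presets) resolve, air spectra (Ω·Q ≈ 0.07) do
not.

Absolute amplitudes are arbitrary units — the transduction gain of a real
vibrometer is unknown — so all inference uses only f₀ and Q.

## Inference

Classification normalizes each mode-ratio axis by the beam-string gap
(≈0.76 for f₂/f₁, ≈0.46 for f₃/f₂) and assigns the nearer theoretical
point, returning `indeterminate` when the two normalized distances differ
by less than the propagated ratio uncertainty.

The effective modulus comes from ordinary least squares of f₁ on R/L²
through the origin (the unstressed-beam law has no intercept); a free-
intercept diagnostic fit is available to expose systematic offsets. The
slope inverts to E = ρ(4π·slope/λ₁²)², with first-order error propagation.
Two per-condition variants are reported: the pooled-regression E (one slope
per condition) and the mean/std of per-bundle inversions (each bundle
inverted individually), the latter matching an error bar defined as the
standard deviation over measurements. Densities default to 1700 kg/m³ for
pristine and 1500 kg/m³ for intercalated bundles; every E report names the
density used, and E scales linearly with it.

Titration analysis groups dose-labelled measurements (4×, 2×, 1×, 0.5×,
0.05×, 0.01× or numeric), checks the below-saturation trend (lower dose →
higher E, toward pristine) and flags a plateau when the at/over-saturation
means differ by no more than their pooled standard deviation.

## Steered-MD post-processing

Strain is engineering strain in percent of the starting length; stress is
force over the helix cross-sectional area; E_SMD is the slope of the
weighted least-squares stress-strain fit (weights are inverse-variance from
the per-force replicate standard errors), times 100 to undo the percent
convention — stated explicitly because a silent 100× error here is the
classic failure mode. Replicates are averaged per force level before the
fit. Defaults that are *choices*, not measurements: L₀ = 22.4 nm (66 bp at
the 3.4 Å B-form rise of the simulated starting structure) and helix area
π·(1 nm)² ≈ 3.14 nm². Absolute E_SMD scales inversely with the chosen
area, so only recovery of generator inputs and between-system ordering are
claimed, never absolute reproduction of any particular simulation study.
Hydrogen-bond loss is the percent change of the mean count between two time
windows (we use the first and last 2 ns); it is antisymmetric under window
swap only up to the change of denominator.

## Synthetic-data generator

The generator emulates the study conditions end to end so that every stage
is testable offline:

* geometry: L ~ U(10, 15) µm, nominal d ~ U(30, 100) nm — the stated
  experimental ranges, with no further distributional information, hence
  uniform; the resonating diameter deviates from the nominal (manifest) one
  by a fractional N(0, 7%) to emulate diameter metrology variability;
* condition presets (generator *inputs*, used as recovery ground truth):
  E = 5.3 / 8.1 / 12.6 / 2.6 GPa and ρ = 1700 / 1500 / 1500 / 1500 kg/m³
  for pristine / YOYO-1 / GelRed / CisPt; asymmetry Ω = 1.15% × (1.00 /
  1.32 / 1.82 / 1.21); air Q = (5, 8, 8) per mode, vacuum Q = 250;
* population spread: per-bundle E ~ N(E₀, 20%·E₀) truncated positive. The
  20% CV is a free calibration of the generator chosen to give error bars
  of the reported order of magnitude; it is not a measured value;
* measurement noise: 1.5% fractional jitter on each air mode frequency
  (independent per mode) and on the vacuum doublet (common-mode for the
  pair, because splitting is read within a single spectrum and drift moves
  both peaks together). The true per-bundle measurement uncertainty is
  unpublished; 1.5% is a flagged calibration knob;
* per-bundle asymmetry is deterministic per condition by default
  (`omega_cv = 0`): only condition-average Ω values are reported anywhere,
  so inventing a per-bundle spread would add an unverifiable parameter;
* spectra: air grids span 0.5·f₁ to 1.25·f₃ with 2400 points, vacuum grids
  ±4% around the doublet with 1600 points — both comfortably above the 50
  points-per-bandwidth sampling contract; additive white Gaussian amplitude
  noise at SNR 20 (peak/σ); mode drive amplitudes decrease with mode index.

What the generator does **not** emulate: 1/f noise and drift, thermal
(Brownian) background, humidity/temperature dependence of E, nonlinear
(Duffing) response, and any chemistry. Passing recovery tests therefore
demonstrates that the inference chain is unbiased and correctly propagates
the modelled noise — not that real vibrometer data carry no other
systematics.

SMD tables are generated from exact linear elasticity at preset moduli
(1.50 / 2.61 / 1.11 GPa saturated DNA / DNA/YOYO-1 / DNA/CisPt; 1.98 /
1.23 GPa sub-saturated), 8 uniformly spaced forces (50-400 pN) × 3
replicates, with 2% relative Gaussian strain noise; zero-force rows are
exactly unstrained. H-bond series are linear decays with integer jitter
whose first/last-2 ns window means give ~30% loss (pristine), near
stability (YOYO-1) and >40% loss (CisPt).

## Problem sizes and determinism

Recovery studies in the test suite use 25 bundles per condition for
modulus recovery (3 full raster-and-fit replicate runs, plus 100
frequency-level Monte-Carlo populations for the ordering statistic — the
peak-fit frequency error, bounded at ≤0.1% by the round-trip tests, is an
order of magnitude below the 1.5% measurement jitter, so the frequency-
level path is statistically equivalent for condition means), 10 bundles per
condition for splitting recovery, and 200 seeds for the spectrum round-trip
and SMD recovery statistics. Every random draw flows from an explicit
integer seed through `numpy.random.default_rng`; identical seeds give
byte-identical outputs, and each CLI run logs its seed and parameters in a
JSON run report sufficient to regenerate the outputs bit-identically.

## Known limitations

* The beam model is linear Euler-Bernoulli: no shear deformation (fine for
  L/d ≈ 100-500), no torsional or longitudinal modes, no Duffing response.
* Q extraction by 3 dB bandwidth is biased by a few percent at Q ≈ 5 due to
  lineshape asymmetry; the fit-based Q is preferred and the two are only
  required to agree within 5%.
* The modulus is *effective*: a composite-bundle property that absorbs
  inter-strand interactions and Poisson effects; it is not the modulus of a
  single duplex.
* Absolute SMD moduli depend on the chosen helix cross-section area and L₀.
* The string-limit check uses clamped-clamped eigenvalues inside the
  tension factor; the crossover region between beam and string is therefore
  approximate, which is why the classifier carries an `indeterminate` band.
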