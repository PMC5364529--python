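# Methods

This note records the models implemented in `knotfold`, their assumptions,
the defaults that matter, the numerical strategy, and the known limits of
validation against synthetic data.  Units throughout: energies in
kcal·mol⁻¹, rates in s⁻¹, denaturant in mol·L⁻¹, temperatures in kelvin;
the gas constant is fixed at R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and the default
analysis temperature is 298 K exactly (configurable via `Conditions`).

## Equilibrium unfolding

The two-state description uses the linear-extrapolation model (LEM):
ΔG(D) = ΔG_H₂O − m·D, with the denatured fraction given by the Boltzmann
two-state population.  The observed signal of each spectral channel is the
population-weighted sum of linear native and denatured baselines
(y_N + s_N·D and y_D + s_D·D).  Nothing in the published analysis
constrains the baseline form; linear baselines are the field's default and
are consistent with the self-consistency of the fitted m, ΔG, and [D]₅₀%.

The global fit shares (ΔG_H₂O, m) across all channels of all series
(fluorescence and CD together) and keeps the four baseline parameters per
channel free.  Numerically this is solved by **variable projection**: for a
trial (d₅₀, m) the baselines are an exact linear least-squares subproblem
per channel, so the nonlinear search runs over just two parameters, from
multiple starts (midpoint initialised at the concentration of steepest
signal change, m ∈ {1, 2, 4}).  A full-parameter refinement then supplies
the Jacobian-based covariance for the standard errors.  A fit whose
midpoint falls outside the measured concentration range is rejected as
"transition not bracketed"; a numerically singular Jacobian raises an error
naming the unidentifiable parameter.

**SVD component count.**  Titration matrices (wavelength × concentration)
are decomposed with full SVD.  "Significance" of a component is judged by
the first-order autocorrelation C = Σᵢ wᵢwᵢ₊₁ of each unit-normalised
singular vector (the Henry–Hofrichter diagnostic): a component counts only
when **both** its spectral (U) and its titration-coefficient (V) vectors
exceed the threshold (default 0.8), counted contiguously from the first
component.  Applying the threshold to both vectors is the stricter of the
reasonable readings and is robust: smooth signal vectors autocorrelate near
1, white-noise vectors near 0.  The count is invariant to positive
rescaling of the data.

The wavelength-of-maximum-emission variant fits the same LEM with scalar
baselines.  The peak-position midpoint coincides with the population
midpoint only when the native and denatured bands have comparable
amplitudes; with unequal bands it is systematically shifted, which is why
the full-spectrum global fit is the primary analysis.

## Stopped-flow kinetics

Traces are fit to y(t) = y∞ + ΣAᵢexp(−kᵢt) with 1–3 phases.  Amplitudes
and offset are linear and solved by projection; the search runs over
log-rates from eight log-spaced multi-starts.  Phase count selection uses
the extra-sum-of-squares F test (α = 0.05) with three guards: (i) rates
closer than 1.5× are deemed unresolved and the simpler model kept, (ii) a
candidate phase whose amplitude is below 2% of the signal span is rejected,
and (iii) once the RSS reaches the numerical floor (10⁻⁸ of the signal
span, squared) no further phases are tried — without (iii) the F test on
noise-free data accepts arbitrarily small RSS reductions.  Rates above the
sampling Nyquist bound (1/(2·Δt_min)) raise an error; flat traces return a
flagged single-phase fit with near-zero amplitude.  Points before the
instrument dead time (default 2 ms, configurable per trace) are discarded.

Chevron fitting minimises residuals in log₁₀(k_obs): the four kinetic
phases span six orders of magnitude in rate, so linear-space least squares
would be dominated entirely by the fastest points, and multiplicative
(log-normal) rate errors are the realistic stopped-flow noise model.  Both
arms must be populated (≥ 4 points each); otherwise the error names the
missing arm.  Parameters are (log₁₀k_f, m_f, log₁₀k_u, m_u), initialised
from straight-line fits of each arm.  Derived ΔG, m_kin, and [D]₅₀% satisfy
their defining identities exactly by construction; their standard errors
are propagated from the covariance.

A note on the fastest phase: its published m_kin (1.73) is inconsistent
with its own published m_f and m_u (|m_f| + m_u = 2.46) and with its
published midpoint (2.52 M, which follows from 2.46).  The package always
derives m_kin from the fitted arms; the discrepancy is pinned by a
regression test rather than silently corrected.

## Double-jump analysis

Mixing arithmetic propagates volume-weighted denaturant and protein
concentrations through an ordered list of dilution steps; the presets
mirror the three experiment modes (single jump 10:1; interrupted refolding
1:5 then 1:1; interrupted unfolding with the roles swapped — the modes
share all machinery and differ only in the mixing scheme).

Shared-rate global fitting keeps one rate set across all aging times with
per-trace linear amplitudes/offsets (variable projection again).  Amplitude
build-ups versus t_age are fit to A∞(1 − exp(−k·t_age)); a phase is
lag-flagged when a delayed-onset (sequential two-step) model improves the
fit at α = 0.05 by the F test — a statistical criterion, because the
published lag is described as barely visible.

The linear three-state scheme A ⇌ B ⇌ C (A = denatured, C = native;
initial state pure A by default) is characterised analytically: relaxation
rates are the negated non-zero eigenvalues of the 3×3 rate matrix, and
populations come from the eigendecomposition, verified against ODE
integration to 10⁻⁸.  Microscopic rates are fit to the two observed
build-ups (fastest phase ↦ intermediate population, slower phase ↦ native
population) by multi-start least squares in log-rate space, with an F-test
comparison against a two-state alternative reported via `preferred`.

**Identifiability.**  Build-up amplitudes are assumed to be on the
population scale (normalise by the total amplitude change first); freeing
per-phase scale factors introduces a known trade-off with the back-rates.
Even on the population scale the back-rate k_BA is only weakly determined:
with the default generator rates (0.03/0.003/0.3/0.03 s⁻¹) its contribution
to the observables is marginal, and at 10% amplitude noise its recovery can
be off by several-fold while k_AB, k_BC, k_CB and both observable
relaxation rates recover within a factor of ~1.5.  This mirrors the
original analysis, which reports its three-state fit as noisy.

## Hydrogen–deuterium exchange

Per-residue intensity decays are fit to I₀·exp(−k·t) with the floor fixed
at zero (a fully exchanged cross-peak vanishes; a free floor is optional).
Series decaying by less than 2% of the maximum intensity are reported as
below the detection bound (5% decay over the observation window) rather
than as rate estimates, and protection factors computed from them are
lower bounds.

Intrinsic rates use the additive nearest-neighbour log-factor model with
the poly-DL-alanine reference parameters (bundled as
`data/intrinsic_exchange_factors.csv` with provenance header): acid, base,
and water terms, each scaled by 10^(left+right) neighbour factors, with
terminal-group corrections for the second and last residues and Arrhenius
temperature scaling (Ea = 14/17/19 kcal·mol⁻¹ for acid/base/water) from the
293 K reference.  The D₂O ion product is held at pK_D = 15.05.  Titratable
side chains are used in their dominant neutral-pH forms (Asp⁻/Glu⁻, neutral
His, reduced Cys); the table's His/Pro/termini entries follow the parameter
set distributed with the original spreadsheet and may differ in the last
digit between distributions.  Protection-factor recovery is insensitive to
such differences because PF = k_int/k_obs uses the same k_int on both sides
of the synthetic round trip.  pD is taken as the glass-electrode reading by
default (`pd_correction = 0.4` applies the conventional correction); the
experiments report uncorrected buffer pH, so the default records it as-is.

First residues and prolines carry no exchangeable backbone amide and raise
an explicit error; residues with incomplete series are skipped and logged
by the CLI, mirroring partially resolvable assignments.  Profile comparison
reports median log₁₀PF per secondary-structure segment and orders proteins
by overall median.

## Thermal denaturation

ΔG(T) = ΔH_m(1 − T/Tm) − ΔCp[(Tm − T) + T·ln(T/Tm)], zero at Tm by
construction and verified against Kirchhoff/van't Hoff integration.  ΔCp is
**fixed** (default 0) unless explicitly freed: a melting curve spanning
~55 K constrains ΔCp poorly, and no thermal ΔCp values are reported for
these proteins.  Normalisation to fraction folded happens internally
through fitted linear baselines, making the fit invariant to affine
rescaling of the raw CD signal.  Thermal reversibility is assumed (the
two-state treatment requires it).  Tm shifts between apo and ligand-bound
melts carry errors propagated in quadrature; absolute Tm accuracy is
validated only property-based, since the reference results report shifts
(≈ +2.2 K for UCH-L1 with ubiquitin), not absolute melting temperatures.

## ITC binding thermodynamics

Expected injection heats use the standard perfusion-cell displacement
bookkeeping — cell species diluted by (1 − v/2V₀)/(1 + v/2V₀), titrant
accumulating as (v/V₀)/(1 + v/2V₀) — the closed-form one-site quadratic for
the bound concentration, and the mid-injection correction for heat carried
out with the displaced volume.  The closed form is verified against a
mass-balance bisection oracle to 10⁻⁹.  Single-isotherm fits estimate
(n, Ka, ΔH, offset); the Wiseman c-value outside 0.5–1000 flags the fit as
poorly constrained rather than failing it.  The temperature-series global
fit runs over (ΔH₀, ΔS₀, ΔCp) with residuals on ΔH and RT·lnKa (so both
observables contribute in kcal), at reference temperature T₀ = 298.15 K
(standard conditions).  Two temperatures leave ΔCp unidentifiable and raise
an error; excluding an outlier temperature from the input list is the
caller's decision, not an automatic rule.  The tabulated binding entropy is
stored as ΔS in cal·mol⁻¹·K⁻¹ and reported also as TΔS, with
ΔG − ΔH + TΔS ≡ 0 as a bookkeeping invariant.

## Contact order

RCO = (1/(L·N))·Σ|i−j| with all heavy-atom pairs within 6 Å, sequence
separation ≥ 2, each qualifying atom pair counting once — the original
contact-order convention; cutoff, separation, and chain are CLI-exposed
because published values rarely state their convention and the result is
convention-sensitive at the ±0.01 level.  L is the count of resolved
residues with numbering compacted across gaps.  The k-d-tree contact search
is verified against an O(n²) all-pairs oracle, and RCO against rigid-body
invariance.  The cross-paralog reference values (≈0.137/0.144/0.139) refer
to specific deposited structures and are not re-derived here, since the
package ships no third-party coordinates.

## Synthetic data: what it does and does not emulate

Generators produce: two-state titration spectra from two Gaussian emission
bands (native 330 nm; denatured red-shifted to 350 nm and weaker) whose
weights follow the two-state populations, with linear amplitude drift as
baselines, 41 points over 0–6 M (the 2.5% increment scheme); kinetic traces
as exponential sums sampled log-uniformly behind a 2 ms dead time; chevrons
with multiplicative (log-normal) rate noise, 15 points per arm over
0.7–3 M and 4–8 M; interrupted-refolding series by exact three-state
propagation over a log-spaced 10 ms–100 s aging grid; HDX decays from a
per-residue log-PF field; Gibbs–Helmholtz melts over 298–353 K; one-site
isotherms at 27.5/275 μM cell/syringe concentrations.  Default noise levels
are proportional Gaussian with CV 1% for spectra and traces, 2% for ITC
heats, 5% for HDX intensities — instrument-grade values.  Every generator
takes a seed and is byte-reproducible; the temperature series derives one
substream per isotherm.

Not emulated: photophysical artefacts (photobleaching, inner-filter
effects, PMT nonlinearity), mixing artefacts in the dead-time region,
baseline drift correlated in time, NMR peak overlap, heats of dilution
beyond a constant offset, and shot noise.  Parameter-recovery tests
therefore validate the estimators under the stated noise model, not
robustness to structured instrument artefacts.

## Numerical conventions

* All nonlinear fits: `scipy.optimize.least_squares` (trust-region
  reflective), tight tolerances (xtol ≲ 1e-13), multi-start over log-spaced
  rate/parameter grids; linear subproblems by `numpy.linalg.lstsq`.
* Rates are optimised in log space wherever they are positive by model.
* Standard errors: Gauss–Newton covariance s²(JᵀJ)⁻¹ at the optimum;
  singular Jacobians raise errors naming the worst-determined parameter.
* Degenerate inputs (flat traces, constant matrices, non-decaying series,
  flat isotherms) return flagged results or typed errors rather than
  numeric garbage; tie-break conventions: multi-exponential rates stored
  descending, phase labels report slowest-first.
* Fixed seeds derive all synthetic randomness via
  `numpy.random.default_rng`.
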