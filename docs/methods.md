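# Methods

This note documents the models implemented in `piezodyn`, the defaults and
numerical choices behind them, what the synthetic-data generator emulates,
and the known limits of what the validation studies demonstrate.

## Units and constants

All internal quantities use one convention: energy transfer ħω and Lorentzian
HWHMs in meV, q in Å⁻¹, time in ps, length in Å, temperature in K, pressure
in bar, ΔH in kJ/mol, ΔS in J/(mol·K).  Activation energies are reported in
both kJ/mol and kcal/mol (1 kcal = 4.184 kJ).  Constants: ħ = 0.6582119
meV·ps, k_B = 0.0861733 meV/K, R = 0.0083145 kJ/(mol·K).  Positive ω means
energy transferred to the sample.

## Reduction chain

Raw measurements (sample, empty cell, buffer/D₂O, vanadium) carry a
transmission t ∈ (0, 1].  The corrected signal is

    (I_s/t_s − I_ec/t_ec) − (1 − f)·(I_b/t_b − I_ec/t_ec)

where f is the volume fraction of buffer displaced by the protein.  The
default f = c·v̄ = 0.120 g/mL × 0.73 mL/g ≈ 0.0876 corresponds to a
120 mg/mL protein solution with a typical partial specific volume; it is a
configurable argument because the subtraction scale is a modelling choice,
not a measurement.  Negative channels after subtraction are clipped to zero
and counted in the log.  No Paalman–Pings attenuation or multiple-scattering
corrections are applied; cell geometry enters only through the transmissions.

Vanadium, an almost purely elastic incoherent scatterer, provides both the
per-detector efficiency (each q channel is divided by the vanadium elastic
intensity, or its ω-integral for time-of-flight data) and the resolution
function (its area-normalized ω-profile per q).  Detailed balance is removed
by multiplying S(q, ω) with exp(−ħω/2k_BT), which maps the quantum asymmetry
S(−ω) = e^(−ħω/k_BT)S(ω) onto the symmetric classical form.

Temperature binning uses 10 K bins anchored at the scan-start temperature,
inverse-variance weighting within each bin, and the weighted mean temperature
as the bin label.  Up- and down-scans are merged only after a hysteresis
check: if more than 1% of (T, q) points differ by more than 3σ the merge is
refused and the discrepancy map returned.  Both thresholds are package
choices; the underlying requirement is only "verify absence of hysteresis".
Energy rebinning is flux-conserving (native points are treated as averages
over their own bins, so the integral over any shared interval is preserved);
the default analysis window is ω ∈ [−1.5, +1.5] meV in 0.02 meV steps with q
restricted to 0.6–1.8 Å⁻¹.

Error propagation is first-order quadrature throughout.  A 2000-replicate
Monte-Carlo of the full chain reproduces the propagated σ within 10% per
channel in the regime where the clip-at-zero never triggers; on
background-dominated channels (|signal| ≲ σ) the clipping truncates the
distribution and the empirical spread falls below the propagated value —
an intended consequence of the clipping rule, not an error-model defect.

## Two-state elastic fitting

The global fit at one pressure shares (d, ΔH, ΔS) and one overall scale
across all temperatures, with ⟨Δx₀²⟩(T) free per temperature; weights are
1/σ².  The model is multimodal in (d, ΔH), so the fit restarts from a
deterministic grid d ∈ {0.5, 1, 1.5, 2, 3} Å, ΔH ∈ {5, 10, 20, 40} kJ/mol,
ΔS ∈ {0, 20, 50} J/(mol·K); the grid is abandoned early once a start reaches
a statistically adequate χ² (χ² ≤ dof + 3√(2·dof)), which makes noiseless
and well-behaved fits essentially single-start.  An overall scale parameter
absorbs the arbitrary normalization left after vanadium division; anchoring
S(q→0) = 1 instead is available via `fix_scale`.

Two structural degeneracies are handled explicitly:

* the model depends on ΔH, ΔS only through p₁p₂, which is invariant under
  (ΔH, ΔS) → (−ΔH, −ΔS); solutions are canonicalized so that well 2 is the
  ground state (ΔG ≥ 0 at the mean temperature);
* when d ≈ 0 the thermodynamic parameters carry no information.  Parameter
  covariance is computed from the SVD of the Jacobian with near-null
  directions assigned effectively infinite variance, so unidentifiable
  parameters surface as `*_unidentifiable` flags rather than confident
  numbers (a plain pseudo-inverse would silently report tiny variances).

The total MSD adds the inter-well term p₁p₂d²/3.  The resilience is reported
as the pseudo force constant 2k_B/(dΔx_tot²/dT) in N/m (k_B in J/K, slope
converted to m²/K); a flat curve raises an overflow flag instead of a number.
The dynamical-transition test fits a continuous two-segment (hinge) model at
every interior data temperature and compares the best hinge against the
single line with an F-test (α = 0.05).  Because the breakpoint is searched,
the test is mildly anticonservative (measured false-positive rate ≈5%
against the nominal 5% at 9 points and 3% noise); detection is only reported
below α, otherwise the curve is declared linear.

## QENS fitting

The spectral shape is A₀(q)L(ω; Γ_j) + (1−A₀)L(ω; Γ_j + Γ_loc) with
unit-area Lorentzians; it integrates to 1 over ω for every q.  The fitted
amplitude is scale·exp(−q²⟨u²⟩) (a Debye–Waller-like q-dependent factor);
⟨u²⟩ can be frozen via `fix_dw` to reduce the fit to the three physical
parameters plus one scale.  Positive parameters are fitted in log space;
multi-starts come from a deterministic 3×3×3 grid over decades
(τ ∈ {0.2, 2, 20} ps, ⟨l⟩ ∈ {0.3, 1, 3} Å, Γ_loc ∈ {0.03, 0.3, 3} meV) with
the same early-stop rule as the elastic fit.

Resolution convolution is discrete linear convolution on the regular ω grid
(FFT, zero padding, cropped back to the window, ×Δω).  The operator is
linear and, for instrument-like resolution profiles, preserves the model
area up to the mass exchanged across the window edges; for Lorentzian wings
this exchange is O(10⁻⁴) of the area, which cancels in fitting because data
and model are generated/evaluated with the same operator.  Against closed
forms the operator reproduces the summed-HWHM Lorentzian⊗Lorentzian width to
<0.1% and the Gaussian⊗Lorentzian Voigt peak to ~10⁻¹⁰ relative.

**EISF extraction.**  A₀(q) is the ratio of the elastic-window integral
(default half-width: one resolution FWHM at that q) to the total integral.
The raw ratio is biased because both spectral components leak across the
window, so a corrected estimate inverts

    raw = (A₀·u + (1−A₀)·v) / (A₀·U + (1−A₀)·V)

where u, v (U, V) are the window (whole-grid) integrals of the two
resolution-convolved components, with widths taken from a light per-q
two-Lorentzian pre-fit.  The inversion is exact on noiseless data.  Its
error budget combines the amplified raw-ratio counting error with the
pre-fit width covariance pushed through the inversion; this calibration was
checked against the empirical scatter over Monte-Carlo replicates (reported
σ within ~30% of the true spread per channel).  Both raw and corrected
estimates are returned.

**Uncertainties.**  Because A₀(q) enters the global fit as fixed numbers,
the statistical covariance alone understates the parameter errors.  The fit
therefore adds the EISF contribution through the sensitivity
∂p̂/∂A₀ = −(JᵀJ)⁻¹Jᵀ(∂r/∂A₀): with it, the joint 2σ region of (τ, ⟨l⟩)
covers the truth in 20/20 Monte-Carlo replicates at 10⁴ counts per q
channel, against 1/20 without it.

**Model-free survey.**  Per q, an explicit resolution-shaped elastic line
plus n = 1…3 free Lorentzians are fitted; the component count is chosen by
the summed small-sample-corrected AIC.  Width-versus-q trends are classified
flat or saturating by comparing a constant against a jump-diffusion-shaped
curve with the scale-invariant Gaussian AICc (n·ln(RSS/n) + penalty), since
fitted widths carry no error bars.

## EISF geometry

A₀(q) = p + (1−p)[s·j₀²(qR/2) + (1−s)(1 + 2j₀(q·a_M))/3] with
a_M = 1.715 Å fixed.  The source rendering of the confined-motion term is
ambiguous between j₀²(qR/2) and j₀²(qR); the package defaults to the former
and exposes `aj_form="full"` for sensitivity analysis.  Fits are bounded
(p, s ∈ [0, 1], R ∈ (0.5, 20) Å) with multi-start over R ∈ {1, 2, 4, 8} Å;
s ≈ 0 leaves R unconstrained and is flagged `radius_unidentifiable`.

The p–s–R fit is intrinsically ill-conditioned on a 0.6–1.8 Å⁻¹ window: at
5% noise on 13 points the long-run median radius error is ≈16% under the
default form (a maximum-likelihood oracle started at the truth achieves the
same, so this is an identifiability floor, not an optimizer artifact), and
≈5% under the `full` form whose first j₀ zero falls inside the q window.

## Thermal laws

Arrhenius fits are exact weighted linear regressions of ln y on 1/T, with
E_A = ∓slope·R depending on whether the observable is a rate (Γ_loc) or a
time (τ).  VFT fits profile the Vogel temperature over [0, T_min − 20 K]
with an exact weighted linear sub-fit of ln τ versus 1/(T − T₀) at each
candidate, refine the minimum, and propagate the T₀ uncertainty from the
profile curvature.  T₀ at its bound flags weak identifiability; a slope
D·T₀ consistent with zero flags reduction to an Arrhenius/constant form.
VFT is ill-conditioned on an 80 K window: at 5% noise even the
maximum-likelihood estimator shows ~35% median error on D and ~19 K on T₀,
and the implementation is validated for parity with that oracle rather than
against a tighter target.

Model selection between Arrhenius and VFT uses the Gaussian AICc with
unknown error scale, n·ln(χ²/n) + 2k + 2k(k+1)/(n−k−1).  The unknown-scale
form makes the comparison invariant under a common mis-scaling of the
supplied error bars — relevant because fixed-EISF fits understate τ errors —
and |ΔAICc| < 2 (or fewer than 5 points) yields "indistinguishable" rather
than a choice.

## Synthetic data

The generator emulates a backscattering-style elastic scan (q = 0.2–4.5 Å⁻¹,
25 points; 283–363 K in 10 K bins; 1/150/300/600 bar) and a time-of-flight
QENS map (q = 0.6–1.8 Å⁻¹, 7 channels; ω = ±1.5 meV in 0.02 meV steps;
Gaussian resolution of 70 µeV HWHM, with 8 µeV available for the elastic
gate).  Raw data are built forward from the model: signal plus smooth
empty-cell and broad-Lorentzian buffer backgrounds (artifact shapes chosen
to exercise the reduction, not physical claims), a cosine detector-efficiency
profile, transmissions, detailed-balance asymmetry, and Poisson counting
noise (Gaussian and noise-free options exist).  Every dataset embeds its
ground truth and seed; regeneration is bit-identical.

Two presets encode the qualitative contrast the pipeline should resolve:
`piezophile_like` (Arrhenius τ(T), pressure-flat d and R) and
`piezosensitive_like` (VFT τ(T) with pressure-increasing fragility,
pressure-decreasing d, pressure-increasing R).  Trend directions are the
designed behaviour; the magnitudes are fabricated defaults and are flagged
as such in the embedded metadata.  Preset counting statistics are 10⁵
counts per q channel, matching measurements whose point errors are at the
percent level; the deliberately harsher 10⁴-count level is reserved for the
recovery studies.

What passing the synthetic studies does **not** show: the generator draws
from the same model families the fits assume, so the studies quantify
identifiability, noise robustness and implementation correctness — not
model adequacy for real proteins.  Multiple scattering, attenuation,
instrument-geometry effects, q-dependent resolution shapes and
non-Lorentzian quasi-elastic broadening are all outside the emulation.

## Validation-study sizes

The studies in `piezodyn.studies` (shared by the test suite and
`scripts/acceptance.py`) use: 50 replicates at 2% noise for the two-state
recovery (9 T × 25 q); 20 replicates at 10⁴ Poisson counts per q channel for
the Hall–Ross recovery (with A₀ extracted, not taken from truth);
50 replicates at 5% noise on 13 q points for the EISF geometry; 100
replicates per law at 3% noise for thermal-law discrimination; 100
replicates each for breakpoint specificity (pure line) and sensitivity
(slope ratio 3 at 320 K, detection within one 10 K bin).  The sequence
study aligns a synthetic 161-residue ortholog pair carrying the sixteen
documented substitutions planted at their printed positions — a labelled
stand-in for the deposited sequences, which require a download.

## Known limitations

* The QENS analysis fixes A₀(q) from integration; although the EISF
  uncertainty is propagated into the parameter errors, correlated A₀ biases
  (e.g. from the window choice) propagate into τ undetected.  The elastic
  integration window is exposed as a parameter for sensitivity analysis.
* The breakpoint F-test does not correct for the breakpoint search;
  significance levels are approximate.
* The hinge-model breakpoint and the resilience slope both assume the MSD
  error bars are trustworthy; fitted ⟨Δx₀²⟩ errors at different temperatures
  are treated as independent.
* Lorentzian spectral wings extend beyond any finite analysis window; area
  bookkeeping is exact only for the window contents, and all comparisons
  (generation, fitting, EISF correction) therefore use the same windowed
  convolution operator.
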