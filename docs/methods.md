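# Methods

This note documents the models implemented in `qclpas`, the default
parameters and why they have the values they do, what the synthetic data
emulate (and do not), and the numerical and design choices that were
genuinely open.

## Photoacoustic signal model

Amplitude-modulated photoacoustic detection converts modulated optical
absorption into a periodic pressure signal at the cell's first longitudinal
resonance.  The magnitude is proportional to

```
pa ∝ C_cell · ε_relax · α · P0,     C_cell = (γ−1) · (Q/f_res) · L_R/(2·V_R)
```

with `α` the absorption coefficient of the gas matrix (cross-section ×
number density), `P0` the mean optical power, and `C_cell` the cell constant
built from the heat-capacity ratio γ, the resonance quality factor Q, the
resonance frequency `f_res` and the resonator geometry.  The relaxation
efficiency `ε_relax` — the fraction of absorbed energy thermalized within a
modulation period — is treated as constant over the <1 cm⁻¹ emission range
and across the breath matrix variations considered; it is therefore
unidentifiable from the amplification factor and folded into it.  This
constancy is an *assumption* of the model (empirically supported by the
additivity of sum spectra), not a derived property; matrices with strong
relaxation promoters/quenchers outside the considered set would violate it.

### Forward model over the current sweep

A spectrum is indexed by high-level current `I` (350–495 mA in 1 mA steps,
146 points).  For each `I` the model evaluates

```
pa(I) = q(I) · P0(I) · ⟨E_I, Σ_c α_c⟩ + b(I)
```

* `E_I`: Gaussian emission lineshape centred at `ν̃(I) = t0 + t1·I (+ t2·I²)`,
  numerically normalized to unit trapezoidal area on the working grid.  The
  default linewidth is 0.005 cm⁻¹ FWHM — the QCL linewidth is not measured,
  so it is chosen well below the ~48 pm (≈0.007 cm⁻¹) sweep step so the
  stepping, not the linewidth, limits resolution.  When the FWHM is at or
  below the grid spacing the lineshape degenerates to a point mass on the
  nearest grid point (the delta limit used by several tests).
* `⟨·,·⟩`: per-current inner product with trapezoidal weights.  No FFT
  convolution is performed: the instrument only samples the swept centers, so
  a full convolution would compute values never used.
* `q(I) = d0 + d1·I`: amplification in µV/(W·cm⁻¹), lumping cell constant,
  microphone and lock-in gains and `ε_relax`.
* `b(I) = c0 + c1·I + c2·I²`: analyte-independent background from window and
  wall absorption.  By default it is proportional to the optical-power curve
  (the empirical behaviour), normalized to 36 µV at the 495 mA reference.

The model is linear in every component's mixing ratio and additive across
components; the sum-spectrum property of mixtures holds to machine precision
by construction and is verified statistically on noisy campaigns.

### Laser models

* Tuning: linear by default through (350 mA, 1e7/8263 cm⁻¹) and
  (495 mA, 1e7/8270 cm⁻¹), i.e. `t1 ≈ −7.06×10⁻³ cm⁻¹/mA`; a quadratic term
  exists but defaults to zero.  Wavelength increases (wavenumber decreases)
  with current; the mean step is 7000 pm / 145 ≈ 48.3 pm.
* Power: zero at/below the 250 mA threshold, quadratic above, continuous at
  the threshold; the default curve is calibrated so the sweep-mean power is
  80 mW.

### Acoustic model

Resonance frequency responds linearly to the bulk matrix:
`f_res = 5049 Hz + 5.4·X_H2O − 15.0·X_CO2` (X in %v); trace-level analytes
(ppmv) have no effect.  Inverting this for X_CO2 credits the known
water-induced rise back before attributing the remaining deficit to CO2 —
the form that makes inference and prediction exact inverses.  An inferred
value may be negative; it is reported as-is and compared against the CO2
detection limit (≈1.19 %v at 3σ) by the caller.

In dry mixtures CO2 damps the signal by 0.83 %/%v (dominantly a Q-factor
loss, ~1 %/%v); the compensation `U/(1 − X_CO2·b_CO2)` inverts it exactly and
is bypassed for humid matrices, where the effect is absent.  Because no
functional form is available for Q in humid CO2 mixtures, Q there comes from
a small lookup keyed on the CO2 band (0/3/5 %v), seeded from measured humid
operating points; dry Q follows the linear loss law.

γ of a matrix is computed from mole-fraction-weighted molar heat capacities,
`γ = Cp/(Cp − R)`.  The effective Cp of dry synthetic air is **calibrated**
to 29.125 J/(mol·K) so the reference state reproduces γ = 1.3995 exactly
(standard literature Cp values for N2/O2 give ≈1.398 — the reference value
evidently absorbs instrument-specific conventions); CO2 (37.1) and H2O vapor
(33.6) use literature values near 300 K.  The cell-constant change between
two states uses only (γ−1)·Q/f_res — geometry cancels.  Note the printed
per-mixture cell-constant changes in the source characterization are not
reproducible from their own rounded γ/Q/f entries; the package always
recomputes from the state values it is given.

## Preprocessing

* `b_scale(I) = U_BS(I)/U_BS(495 mA)` from raw background samples by default;
  a quadratic-fit smoothing is optional (the choice between raw and smoothed
  scaling curves is genuinely open; raw is the default because it introduces
  no model assumption).  Scaling divides by `b_scale` even where it is small,
  amplifying noise at low currents exactly as the physics dictates; points
  with `b_scale < 0.05` trigger a warning rather than a floor.
* Per-point averaging: each recorded spectrum point is a 16 s average at
  5 Hz (80 samples); calibration points average 20 s (100 samples).
* Lock-in ENBW follows the standard cascaded-RC table: 1/(4τ), 1/(8τ),
  3/(32τ), 5/(64τ) for 6/12/18/24 dB/octave.  At the instrument's setting
  (τ = 5 s, 18 dB/oct) ENBW = 0.01875 Hz.  The convention enters only the
  NNEA computation.

## Metrics

Spectra are compared as intensity vectors.  PCC measures linear association;
SCC is Spearman's rank correlation — exactly `1 − 6Σd²/(n(n²−1))` without
ties, and Pearson-on-midranks with ties (the path taken is recorded).  Both
come from scipy.stats with two-sided p-values.

Allan deviation is the non-overlapping estimator; overlapping/modified
variants are out of scope.  White noise gives a log-log slope of −1/2.

Calibration is ordinary least squares of signal on concentration; the noise
level is 3× the sample standard deviation of a blank series,
`LoD(3σ) = noise/sensitivity`, and

```
NNEA = LoD · N_A · σ(ν̃_Ph) · P0 / (SNR · √ENBW · V_mol)
```

with `V_mol = RT/p` at the cell conditions (35 °C, ambient pressure) and
SNR = 3 matching the 3σ LoD convention (1σ available by parameter).  The
division by √ENBW is the only dimensionally consistent placement, yielding
W·cm⁻¹·Hz⁻¹/², and is corroborated by the published acetone rows: the LoD
and NNEA there imply σ ≈ 1.95×10⁻¹⁹ cm², a plausible value that also makes
the two time-constant rows mutually consistent within ~2%.  The published
ethanol τ = 5 s row is internally inconsistent (133.2 nV / 7.8 µV/ppmv =
17.1 ppbv, printed 11.9); the package always reports the computed ratio.

## Unmixing

Scaled mixture spectra are regressed on per-unit-concentration reference
columns (scaled single-component spectra minus the scaled background,
divided by the reference concentration).  The background is a known constant
column by default (a flag makes it a free parameter).  Estimation is
unconstrained least squares — so null samples scatter symmetrically around
zero — with optional non-negativity for production use.  Designs with
condition number above 1e8 are rejected, naming the most collinear column
pair; ethanol/acetone joint unmixing is supported but inherently
ill-conditioned because both are nearly flat over the sweep, which the
condition number surfaces.  Whether the original two-point regression used
scaled or raw magnitudes is not documented; the package uses scaled spectra,
consistent with how the spectra are presented.

## Model fitting and error attribution

`fit_forward_model` minimizes summed squared magnitude residuals over a
campaign of known-composition spectra.  The canonical free set is the
constant and linear terms of background (c0, c1), amplification (d0, d1) and
transfer function (t0, t1); quadratic terms exist but stay fixed by default.
The covariance is `s²(JᵀJ)⁻¹` with the residual variance `s²`; because the
parameter scales span ten orders of magnitude, identifiability and inversion
work on the column-normalized Jacobian (relative singular-value cutoff
1e-10), and an unidentifiable configuration (e.g. transfer-function terms
against flat absorbers) raises an error naming the null-space parameters.
Relative variances are `var/θ²`, with near-zero parameters flagged undefined
rather than divided by.

The ensemble check samples the Gaussian likelihood under flat (improper)
priors with the affine-invariant sampler (emcee), seeded walkers, 25%
burn-in; for configurations linear in the free parameters the posterior is
exactly Gaussian, so posterior standard deviations must match the
covariance-based errors (verified within 10%).  Parameter excursions outside
the physical domain (emission center off the grid) get zero likelihood.

Base-spectrum correction composes a global multiplicative factor (e.g. a
gas-tank concentration error: a tank holding 96.5% of its assigned
concentration is corrected by scaling the reference spectrum by 0.965) with
a smooth local multiplicative curve over a wavenumber window: a natural
cubic spline through 5 (default) knots with the boundary knots pinned to 1,
so the correction is continuous at the window edges and exactly the global
factor outside.  A multiplicative spline was chosen over an additive one to
preserve non-negativity; the interior knot values are linear in the model,
so fitting them to an observed effective spectrum is a linear least-squares
solve.

## Synthetic data: what it emulates, what it does not

The component library reproduces *shapes and relative scales*, not absolute
database magnitudes:

* water: two pressure-broadened lines at 1209.25 and 1209.77 cm⁻¹ (Lorentz
  HWHM 0.04 cm⁻¹, the 1209.25 line stronger), intensities set so the default
  instrument yields ≈42.7 µV/%v at the 485 mA water peak;
* ethanol: a pedestal of 2.37×10⁻²⁰ cm² plus a 0.3 cm⁻¹-FWHM Gaussian
  feature at 1210.0 cm⁻¹, giving ≈7.8 µV/ppmv at 490 mA;
* acetone: a continuum of 1.95×10⁻¹⁹ cm² at the 490 mA probe point
  (implied by the published LoD and NNEA) with a gentle 3 %/cm⁻¹ slope,
  giving ≈64.1 µV/ppmv;
* CO2: identically zero absorption — it acts only through the acoustics.

The raw lock-in sample noise defaults to 0.3107 µV so that a 20 s / 5 Hz
blank average has a 3σ level of ≈93 nV; spectrum points, being 16 s
averages, carry 0.0347 µV.  Noise is white and Gaussian — real spectra also
contain drift, fringe structure and resonance-tracking residuals that the
generator does not emulate.  Passing tests therefore demonstrate the
*algorithms* (algebra, statistics, inversions, fits) under the documented
conditions, not the instrument's hardware performance on real gas.

Campaign generation stamps each spectrum with the acoustic model's resonance
frequency (pre = post; a drift flag with a 1 Hz default tolerance exists for
real data), applies the dry-CO2 damping where applicable, and is bit-
reproducible from its seeds.  The default plan mirrors the multi-component
measurement series: background, singles (7.9 ppmv ethanol, 2.0 ppmv acetone,
0.9 %v water), pairwise sums, a full synthetic breath with 3 %v CO2, plus
dry-CO2 / humid-CO2 / humid-analyte states.

## Problem sizes and numerics

Defaults used throughout tests and the acceptance script: 146-point sweeps;
a 0.002 cm⁻¹ working grid spanning 1208.9–1210.4 cm⁻¹ (0.0005 cm⁻¹ where the
delta-lineshape inversion is exercised, because the point-mass lineshape
snaps to the grid); 100-replicate Monte-Carlo checks for coverage, unmixing
and similarity; 32 walkers × 3000 steps for the Gaussian-posterior
agreement; 2000 blank averages in the synthetic calibration.  These sizes
keep every statistical estimate's own sampling error well below the
tolerance it is checked against.  Cross-section/line-list/campaign files are
plain text with repr-precision floats, so write → read round-trips are
bit-exact.

## Known limitations

* No time-domain waveform synthesis, lock-in demodulation, cell eigenmode
  simulation, or saturation/photothermal nonlinearity.
* No HITRAN/PNNL download clients; line-mixing, temperature-dependent widths
  and isotopologue bookkeeping are out of scope (the reference conditions —
  296 K, 101325 Pa — and the 35 °C cell state are both exposed because the
  acquisition conditions of measured cross-section tables are generally not
  recorded alongside them).
* Relaxation-pathway physics is deliberately absent; the constant-ε_relax
  assumption bounds the model's applicability to matrices similar to the
  synthetic breath set.
* The machine-learning quantifier that could supersede linear unmixing for
  flat, collinear absorbers (ethanol vs acetone) is future work.
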