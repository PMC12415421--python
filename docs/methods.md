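# Methods

## Physical model

The package works on frequency-sampled complex resistivity fields
ρ̂(ω) = |ρ̂| e^{iφ} as produced by a complex-resistivity inversion of
multi-frequency four-point impedance data (the inversion itself is outside
the package's scope; its output tables are the input format). The complex
conductivity is the reciprocal, σ̂ = 1/ρ̂ = σ′ + iσ″; a capacitive (normal
induced-polarization) response has φ < 0 and σ″ > 0. Phases are radians
internally and mrad in all files.

Each cell's spectrum is modelled as a superposition of N Debye relaxations

    ρ̂(ω) = ρ₀ [ 1 − Σₖ mₖ (1 − 1/(1 + iωτₖ)) ],

with DC resistivity ρ₀ > 0, non-negative chargeabilities mₖ and fixed
log-spaced relaxation times τₖ. Derived integral parameters are the total
chargeability m_tot = Σ mₖ and the chargeability-weighted geometric mean
relaxation time τ_mean = exp(Σ mₖ ln τₖ / m_tot) (natural logarithm; the
result is base-invariant). τ_mean is undefined (NaN) when m_tot = 0.

Relaxation times are mapped to the size of the polarizing structure through
the Schwarz relation for electrochemical polarization around a particle of
radius r, τ = r²/(2D), inverted as d = 2√(2Dτ). D is a configuration scalar
(default 10⁻⁹ m²/s, a typical ion diffusion coefficient; no temperature
correction). Reported cell diameters are truncated to whole micrometres —
the only convention consistent with the printed trio 11/20/25 μm for
τ = 17/50/80 ms.

## Decomposition solver

Substituting cₖ = ρ₀ mₖ makes the Debye model linear in (ρ₀, c₁…c_N):
ρ̂(ω) = ρ₀ − Σₖ cₖ·iωτₖ/(1+iωτₖ). The fit stacks real and imaginary parts of
all frequencies, weights each row by the propagated component error, and
solves a single non-negative least-squares problem (scipy's `nnls`) with a
second-difference Tikhonov penalty √λ·L applied to the c block. Both
components therefore carry information, and non-negativity of m and ρ₀ > 0
are structural.

* τ grid: 20 points per decade spanning a decade beyond [1/(2πf_max),
  1/(2πf_min)] on both sides.
* Error weights: magnitude error a|ρ̂|+b and phase error c|φ|+d (defaults
  a = c = 2 %, b = 0.01 Ω·m, d = 1 mrad) propagated to real/imaginary
  standard deviations; a floor of 10⁻¹² max|ρ̂| prevents zero weights for
  exactly real spectra. Phase errors use |φ| so that the error is a
  magnitude for either phase sign.
* Smoothing: λ = "auto" (the default) applies the discrepancy principle —
  the largest λ with error-weighted RMS ≤ 1, found by 30 bisection steps in
  log₁₀λ over [10⁻¹⁰, 10⁶]. If even the unsmoothed solution exceeds RMS 1
  the unsmoothed solution is returned. λ = 0 disables smoothing; noise-free
  recovery tests use λ = 0 because the discrepancy target presumes noise at
  the error-model level that such data do not contain.
* The restricted variant truncates the spectrum to f ≤ f_max (55 Hz for the
  sugar-beet storage-cell analysis) and rebuilds the τ grid for the
  truncated band; at least 4 frequencies must survive.
* A spectrum with positive phases throughout (inductive-looking) triggers a
  warning and fits m ≈ 0, as it should.

A deliberate property of τ_mean worth knowing: because it is a geometric
mean weighted by chargeability, any mass the fit assigns near the low-τ grid
edge — e.g. the in-band footprint of a fast process whose peak lies above
f_max, or of a polarizable soil background — pulls τ_mean down strongly.
Restricted-band τ_mean values over composite (soil + root) spectra are
therefore relative indicators: they sit an order of magnitude above the
full-band values and rank seasonal presets correctly, but they do not equal
the anomaly's τ parameter. Tests assert the ranking and separation, not a
coincidence with the generator parameter.

## ERI

ERI = log(σ″_HF/σ″_LF)/log(f_HF/f_LF) with defaults f_LF = 3.125 Hz and
f_HF = 1 kHz. Frequencies absent from the grid are resolved by log-log
interpolation (log-magnitude and phase linear in log f), matching the
log-even sampling of surveys; both the interpolated and the exact path are
supported. Cells with σ″ ≤ 0 at either frequency (phases at the noise floor)
are flagged NaN and dropped from zone means with the zone volume
renormalized over the survivors. The phase-ratio approximation
log(φ_HF/φ_LF)/log(f_HF/f_LF) is available behind a flag; the σ″ form is the
definition and the default.

## Zones and aggregation

Root zones collect cells whose centers fall in the closed window
[stem − w/2, stem + w/2] × [0, depth] with w = 0.20 m, depth = 0.25 m (the
excavation volume used for validation). The soil reference collects all
cells at 0.50–1.00 m depth below the maize extent. 2D profile cells carry
V = cell area × 1 m unit out-of-plane thickness; zone means are
volume-weighted, Σ Vⱼxⱼ / Σ Vⱼ. RBD = fresh root mass / V_rz.

## Scheme construction and data quality

For an ordered injection list, every unordered potential dipole {M, N}
disjoint from the current dipole {A, B} is formed (stored with M < N; the
sign of the geometric factor K = 2π/(1/r_AM − 1/r_AN − 1/r_BM + 1/r_BN)
carries orientation). Configurations with |K| > 5 m are dropped (poor
signal-to-noise), as are dipoles of injection i that re-use an electrode
carrying current in injection i−1 (residual electrode polarization;
"previous" means the immediately preceding injection only). Zero-denominator
dipoles are skipped as never acquirable. Filtering of measured impedances
proceeds per frequency: phases > +5 mrad are removed first, then a single
(non-iterated) pass removes phases deviating more than 3 sample standard
deviations (n−1 denominator — ensembles per frequency can be small) from the
mean of the surviving phases. Filters only ever shrink the valid set. Note
that a single outlier among n ≤ 10 values can never exceed 3 sample standard
deviations (the maximum studentized deviation is (n−1)/√n), so the 3σ rule
only bites in larger ensembles — the filter tests use n = 11.

## Synthetic scenes

The generator composes per-cell Debye parameters — a soil background
everywhere plus species-specific anomaly terms inside each plant's window —
runs the forward model on the 23-frequency log-even grid (0.1 Hz – 10 kHz;
analyses cap at 1 kHz), and adds independent Gaussian noise in (magnitude,
phase) space with standard deviations from the linear error models. It
emulates:

* soil: phase decreasing with frequency to ≈ −10 mrad at 1 kHz, levelling
  between 100 Hz and 1 kHz, a few mrad at 1 Hz;
* maize: added high-frequency terms only (τ = 10⁻⁴…10⁻³ s), deepening the
  phase to ≈ −15 mrad at 1 kHz with a monotone decrease above 100 Hz;
* sugar beet: strong high-frequency polarization (to ≈ −25 mrad) plus a
  low-frequency term that grows and slows over the three seasonal presets
  (t1: no distinct peak; t2: peak near 4 Hz; t3: near 2 Hz, deeper).

Per-plant root-system strength is drawn once per scene from U(0.15, 1) of
the full anomaly amplitude — field maize root biomass varies severalfold
between neighbouring plants. Validation masses couple linearly to the
zone-mean root-added high-frequency chargeability (gain 1200 kg/m³ per unit
chargeability, lognormal scatter σ = 0.25 by default), so the rank order of
noise-free masses equals the rank order of true root polarization. Scenes
are byte-reproducible under their seed; all sub-streams derive from it.

What the generator does **not** emulate: spatial error correlation and
smoothing from the tomographic inversion, inversion artifacts (e.g. positive
phase anomalies), electrode-coupling effects, soil heterogeneity and
moisture dynamics. Passing tests therefore demonstrate correctness of the
analysis chain under the stated error models, not field-data performance.

## Problem sizes

Scenes use a 5 cm grid (130×24 cells for the 8-plant maize layout, 195×24
for the seasonal profiles), chosen as typical near-surface inversion
resolution for 25 cm electrode spacing. The phenotyping analysis uses 20
scene realizations; the noisy-recovery study uses 200 noise draws of a
single-term spectrum. Pipeline decompositions default to the root and soil
zone cells (`fit_scope: zones`); `fit_scope: all` fits every cell.

## Known limitations

* The decomposition's λ selection targets RMS = 1 against the configured
  error model; if the model badly misstates the data noise the smoothing is
  correspondingly mis-calibrated.
* τ_mean over composite spectra is a relative indicator (see above).
* The ERI's robustness claim covers multiplicative, frequency-independent
  field changes; frequency-dependent soil dynamics are not compensated.
* 2D profile geometry only; plant windows are applied in profile coordinates
  regardless of out-of-plane offsets (off-plane plants dilute the signal).
* No reciprocal-error estimation and no inductive-coupling correction;
  inputs are assumed already corrected.
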