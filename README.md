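# rootsip

Spectral induced-polarization (SIP) analysis for in-situ root phenotyping.

Field crops polarize: root cell membranes and the electrical double layers
around soil particles store charge under an alternating current, which shows
up as a negative phase shift of the complex resistivity measured between
surface electrodes. `rootsip` implements the analysis chain that turns
multi-frequency complex resistivity tomograms into root traits:

* **Debye decomposition** of each cell's spectrum,

  ρ̂(ω) = ρ₀ · [1 − Σₖ mₖ (1 − 1/(1 + iωτₖ))],

  solved as one error-weighted non-negative least-squares problem, yielding
  the total chargeability m_tot = Σ mₖ (polarization strength) and the mean
  relaxation time τ_mean = exp(Σ mₖ ln τₖ / Σ mₖ) (polarization time scale).
  A low-frequency-restricted variant (≤ 55 Hz) isolates slow processes such
  as the storage-parenchyma polarization of sugar beet.

* **Electrical root index (ERI)**, the log-log slope of the imaginary
  conductivity between a low and a high frequency,

  ERI = log(σ″_HF / σ″_LF) / log(f_HF / f_LF),   (defaults 3.125 Hz → 1 kHz)

  a root-presence proxy that is invariant to frequency-independent
  multiplicative changes of the spectrum (soil water content, temperature).

* **Root-zone traits**: volume-weighted means over the 20 cm × 25 cm
  excavation window around each stem, root biomass density
  RBD = M_root / V_rz, Pearson trait correlations, and the Schwarz relation
  τ = r²/(2D) translating relaxation times into the diameter
  d = 2·√(2Dτ) of the polarizing structure (D = 10⁻⁹ m²/s).

* **Scheme design and data quality**: four-point scheme enumeration with
  geometric-factor (|K| ≤ 5 m) and previous-injection exclusion rules,
  linear magnitude/phase error models, and the positive-phase (> 5 mrad) and
  per-frequency 3σ phase filters.

* **Synthetic field scenes** with exact per-cell ground truth, emulating the
  qualitative signatures of a maize / sugar-beet field trial, so that every
  stage is testable without field data.

## Worked example

Generate the synthetic scenes and run the analyses:

```sh
python analysis/01_simulate_scenes.py
python analysis/02_debye_traits.py
python analysis/03_eri_phenotyping.py
python analysis/04_cell_diameters.py
```

The phenotyping experiment (20 independent 8-plant maize scenes) prints

```
20 scenes: median ERI-RBD Pearson r = 0.828 (range 0.13 .. 0.95)
plant-zone ERI 0.072 vs soil reference 0.040
```

the zone-mean ERI of the maize plants correlates with the true root biomass
density of the generator, and plant zones clearly separate from the deep
(50–100 cm) root-free soil reference. The length-scale translation prints

```
t1: tau_mean = 17 ms -> d = 11.66 um (reported: 11 um)
t2: tau_mean = 50 ms -> d = 20.00 um (reported: 20 um)
t3: tau_mean = 80 ms -> d = 25.30 um (reported: 25 um)
```

i.e. the seasonal increase of the sugar-beet low-frequency relaxation time
maps to storage cells growing from ~11 to ~25 μm (whole-micrometre values by
truncation).

The same steps are available as a CLI: `rootsip simulate`, `rootsip scheme`,
`rootsip filter`, `rootsip decompose`, `rootsip eri`, `rootsip traits`,
`rootsip run` (see `rootsip --help`).

## Layout

```
src/rootsip/     library: spectra, scheme, quality, debye, traits,
                 synthetic, io, pipeline, cli
analysis/        numbered drivers writing tables under results/
tests/           pytest suite (unit, property and acceptance tests)
docs/methods.md  models, parameter choices, numerical details, limitations
```
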