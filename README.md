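# canopylight

Dense beds of submerged macrophytes do not just sit in the underwater
light field — they rebuild it. A canopy-forming pondweed absorbs most of
the photosynthetically active radiation (PAR) within the top decimetres
of the water column and strips red light (650 nm) preferentially over
far-red (750 nm), so a leaf lower on the same stem lives in a dimmer
*and* spectrally different world than its apical neighbours. The plant
answers with depth-graded leaf physiology: light-response capacity,
quenching behaviour and pigment stoichiometry all shift from sun-type
leaves at the surface to shade-type leaves at the base.

`canopylight` is an analysis pipeline for exactly this kind of campaign:
depth-resolved spectroradiometry and PAR profiles, PAM chlorophyll
fluorescence of leaves sampled level by level down the stem, pigment
extracts, and layer-by-layer canopy harvests. A seeded synthetic-data
generator emulates the campaign's statistical structure so every stage
is testable end to end.

## What it computes

**Optics** — the spectral diffuse attenuation coefficient from the
log-linear decay of downwelling irradiance with depth,

    Kd(λ) = −d ln Ed(λ, z) / dz        (OLS over the depth ladder),

the red:far-red shade cue r/fr = Ed(650)/Ed(750) per depth, percent PAR
absorbed by a layer, and half-light / euphotic depths.

**Fluorometry** — from a dark-adapted induction record (F0, Fm) and a
sequence of actinic steps (I, Fs, Fm′):

    Fv/Fm = (Fm − F0)/Fm
    qP  = (Fm′ − Fs)/(Fm′ − F0′)       (F0′ measured, or Oxborough–Baker)
    qN  = 1 − (Fm′ − F0′)/(Fm − F0)
    ETR = (Fm′ − Fs)/Fm′ · I · AF · 0.5     with AF = 0.84

and a Webb exponential-saturation fit ETR(I) = ETRmax·(1 − e^(−αI/ETRmax)),
reporting ETRmax, α and Ik = ETRmax/α.

**Architecture & pigments** — volumetric biomass (g m⁻³), assimilatory
biomass ratio and leaf-area index per 10/20-cm layer; chlorophyll a, b
and carotenoids from 80%-acetone absorbances (Lichtenthaler equations).

**Synthesis** — within-plant potential assimilation ETRmax × LA as
percent of the plant total, per-depth trait coefficients of variation,
Pearson trait × environment (depth, I, r/fr) correlations, and a
standardized PCA of the trait matrix.

## Worked example

```bash
canopylight simulate --density high --seed 1 --out sim_high
canopylight run-all --spectra sim_high/spectra.csv --par sim_high/par.csv --out out_high
```

or, driving the analysis scripts over all four density classes:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_light_field.py
```

which prints (seed 1, default 5% measurement noise):

```
density_class  peak_kd_450_650_per_m  rfr_50cm  absorbed_top10cm_percent  half_light_depth_m
   open_water                  1.341     0.979                    10.860               0.615
          low                  1.341     0.979                    12.896               0.493
     moderate                  3.003     0.484                    17.713               0.357
         high                  1.732     0.460                    66.648               0.063
```

Read: open water halves PAR by ~0.6 m and barely touches the r/fr
ratio; a moderate canopy triples the chlorophyll-band (450–650 nm)
attenuation to ~3 m⁻¹; a dense canopy absorbs two thirds of incident
PAR within the top 10 cm and drives r/fr at 50 cm down to ~0.46 —
deep shade in both quantity and quality. (The high-density peak Kd
shown is the full-profile regression; regressing over the canopy layer
itself, `kd_regression(field, layer=(0, 0.1))`, returns its ~6 m⁻¹
band peak.) `analysis/03_light_curves.py` then recovers the plant's
answer: ETRmax falls ~27% and Ik ~30% from apical to basal leaves, and
`analysis/05_traits.py` shows the top 40 cm of the plant carrying ~56%
of whole-plant potential assimilation.

## Layout

- `src/canopylight/` — the library: `light_field`, `fluorometry`,
  `pigments_architecture`, `traits`, `synthetic`, `io`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and end-to-end round-trip suites.
- `docs/methods.md` — models, calibrations, assumptions, limitations.
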