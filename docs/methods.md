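# Methods

## Scope and data model

The package analyses a depth-structured campaign in a shallow-lake
littoral zone: downwelling spectral irradiance Ed(λ, z) and PAR profiles
measured at nine depths (0, 10, 30, …, 150 cm) inside and outside
canopy-forming pondweed patches of four density classes (open water,
low, moderate, high), plus leaf-level measurements at nine levels down
the stem (interval midpoints 1, 5, 20, 40, 60, 80, 100, 120, 140 cm):
PAM induction records, pigment-extract absorbances, scanned leaf
morphometrics, and 10/20-cm harvest layers per 0.25 m² quadrat.

All irradiance spectra are treated as relative: every derived optical
quantity is a ratio (r/fr, fraction absorbed) or a log-slope (Kd), so
absolute radiometric calibration is never needed. Depths are stored in
cm in files and converted to metres at the I/O boundary. Missing or
non-positive readings propagate as NaN, never as zeros.

## Optical estimators

**Kd(λ).** Per wavelength, minus the ordinary-least-squares slope of
ln Ed against depth over the depths inside the requested layer (default:
the full profile; a two-depth layer reduces exactly to
ln(Ed_upper/Ed_lower)/Δz). Wavelengths with fewer than two positive
readings return NaN. Negative Kd values (noise, internal reflections)
are preserved and reported; a `--mask-negative-kd` flag replaces them
with NaN for presentation. Whether a campaign would regress over all
depths or per-layer pairs is genuinely open; both are exposed through
the `layer` argument.

**r/fr.** Ed at exactly 650 and 750 nm by linear interpolation between
the bracketing grid points (spectrometer grids rarely hit integers);
NaN when Ed(750) = 0.

**PAR summaries.** Fraction absorbed between two depths and the depth
where PAR falls to a given fraction of the surface value both
interpolate in ln(PAR) — exponential attenuation is the physical model.
Surface readings are treated as just-below-surface.

## Fluorescence and light-response fitting

The quenching parameters follow the standard PAM formulary (see README
for the equations), with the empirical leaf absorption factor AF = 0.84
and the factor 0.5 partitioning absorbed photons between photosystems.
When the light-adapted minimum F0′ is not measured it is estimated by
the Oxborough–Baker form F0′ = F0/(Fv/Fm + F0/Fm′); the source
(measured/estimated) is recorded per step. Yields outside [0, 1] and
qP outside [0, 1] are flagged, never silently clipped; Fm′ marginally
above Fm (dark-state noise) is tolerated by the estimator.

**Model.** The ETR light response is fitted with the Webb exponential
saturation curve ETR(I) = ETRmax·(1 − exp(−α·I/ETRmax)); this is the
standard exponential-saturation reading, and the model sits behind a
named option (`light_curve_model="webb"`) so alternatives can be added.
α is reported on the ETR scale (i.e. downstream of AF·0.5), and
Ik = ETRmax/α is always the derived ratio of the two fitted parameters,
never fitted independently.

**Numerics.** Trust-region least squares with both parameters bounded
below by zero; α₀ from the least-squares line through the origin over
the three lowest irradiances, ETRmax₀ = max observed ETR; relative
tolerance 1e−8, at most 10 000 evaluations. Non-convergence returns the
best iterate with `converged=False`. At least four distinct irradiances
including one light-limited point (I < max I/4) are required. On exact
model data the optimum is recovered to ~1e−9 relative and is
independent of initialization.

## Pigments and canopy layers

Extract absorbances convert to µg ml⁻¹ by the Lichtenthaler
80%-acetone equations (chl a = 12.25·A663.2 − 2.79·A646.8;
chl b = 21.50·A646.8 − 5.10·A663.2;
car = (1000·A470 − 1.82·chl a − 85.02·chl b)/198); the equation set is
selectable by name. Per-area values scale by extract volume over disc
area (default: 1-cm-diameter disc). Negative concentrations (turbid
extracts) are kept and flagged.

Layer records divide masses and leaf area by quadrat area × layer
height (0.2 m, or 0.1 m for the apical layer; the true harvested apical
length may override the divisor, since surface-running shoots can
exceed 10 cm). Segment distance-from-apex is identified with water
depth — plants reach the surface in ~1.7 m of water — which is an
assumption, not a measurement. Circularity, when derived, is
4π·area/perimeter².

## Synthesis statistics

Potential assimilation per level is ETRmax × LA, normalised to percent
of the plant total (sums to 100 by construction); the apical share sums
levels ≤ 40 cm. Trait variability is the per-depth sample CV (sd/mean,
reported as a fraction). Trait–environment associations are Pearson r
with unadjusted two-sided p (starred at 0.05/0.01/0.001), computed on
whatever rows are supplied — the pipeline uses depth means — with n
reported. PCA standardizes columns (z-score, population sd) before
decomposition, drops constant columns with a warning, and fixes signs
so each axis's largest-magnitude loading is positive; variance
percentages sum to 100 over all axes. Environment columns (depth, I,
r/fr) never enter the PCA trait set; I is attached to leaf levels by
log-linear interpolation of the PAR profile, r/fr linearly. The per-leaf
qP and qN entering the trait matrix are means over the light steps (the
campaign reports a single value per leaf without stating the reference
step).

## The synthetic generator

The generator is first-class code: it defines the study conditions the
tests and the acceptance run recompute. One integer seed fixes every
output bit-exactly.

**Water.** Kd(λ) is a smooth bimodal spectrum (absorption peaks in the
400–500 and 600–700 nm bands, as humic lake water shows) with two
calibrated integrals: flat-weighted mean over 400–700 nm equal to
ln 2/0.6 m⁻¹ (PAR half-depth 0.60 m) and Kd(650) − Kd(750) =
−2·ln 0.98 = 0.0404 m⁻¹, so that with the surface ratio fixed at 1.0
(approximate daylight; all calibrations are relative to it) open-water
r/fr at 0.5 m is 0.98.

**Canopy.** A chlorophyll-like band — two broad Gaussians (470, 620 nm)
under a sharp red-edge cutoff near 700 nm — added per layer. Low
density adds nothing measurable (sparse plants barely change the
spectrum). Moderate density fills the column uniformly, scaled so the
peak total Kd in 450–650 nm is 3.0 m⁻¹. High density concentrates the
canopy in the top 0.2 m (basal leaves degraded), scaled so canopy
Kd(650) − Kd(750) there is 3.78 m⁻¹, which takes r/fr at 0.5 m to
≈0.46; the resulting in-canopy band peak is ≈5.9 m⁻¹. Only these
calibrated integrals are contractual; the band shape itself is a
modelling choice. Denser classes attenuate at least as much at every
wavelength in the 450–650 band.

**PAR.** Profiles follow a scalar per-class attenuation model rather
than an integral of the synthetic spectra: open water ln 2/0.6 m⁻¹,
low density ln 2/0.5 m⁻¹ (half-light at ~0.5 m), moderate water + 0.8
m⁻¹, high density ln 3/0.1 m⁻¹ in the top 0.1 m (one third of surface
PAR left at 10 cm) and water + 1.5 m⁻¹ below. The spectral and PAR
anchors describe the same physics only approximately, so coupling them
through one spectrum would miss one or the other; the scalar model
reproduces each PAR fact exactly. Surface PAR defaults to 1500
µmol m⁻² s⁻¹ (late-morning mid-summer, mid-latitude).

**Plant.** Nine leaf levels with linear apex→base gradients solved
exactly from the calibration targets: mean Ik over the levels = 160
µmol m⁻² s⁻¹ with basal/apical ratio 0.70 (endpoints ≈184.7 → ≈129.3);
ETRmax 50.0 → 36.5 (ratio 0.73); α = ETRmax/Ik (≈0.27–0.28 on the ETR
scale); leaf area 13.24 cm² at levels ≤ 40 cm and 10.0 cm² below,
which places 55.98% of ETRmax × LA in the top 40 cm. Fv/Fm rises
0.70 → 0.78 with depth. Pigments: total chlorophyll 16 µg cm⁻² at the
surface rising 2.5× linearly over the top 60 cm then flat; chl a/b
3.2 → 2.4 (−25%); chl/car 4.0 → 6.24 (+56%). Leaf dimensions are
ellipse-consistent with the level leaf areas (length 4.8 → 5.8 cm,
width derived), giving circularity falling 0.96 → 0.72 — apical leaves
rounder, basal elongated. Biomass truth per class follows the
qualitative field shapes: uniform ≈270 g m⁻³ (low), bimodal ≈800
surface/≈1000 basal g m⁻³ with the apical leaf fraction at 30% (high);
a dry leaf area:weight of 20.8 cm² g⁻¹ puts peak LAI near 5000 cm² m⁻³.

**Induction traces.** Given a leaf's (ETRmax, α), each actinic step's
target ETR fixes the required yield y = ETR/(I·AF·0.5); Fm′(I) =
Fm/(1 + 0.8·I/(I+300)) is a saturating NPQ surrogate (arbitrary but
harmless — recovery depends only on the ΔF/Fm′ inversion, which is
exact) and Fs = Fm′·(1 − y). A requested yield above 1 raises an error
naming the step. The actinic sequence is 11 geometrically spaced steps
5–787 µmol m⁻² s⁻¹, a protocol assumption matching rapid-light-curve
practice.

**Noise.** Spectra carry multiplicative log-normal noise of
σ_spectral/√25 per emitted replicate (the instrument averages 25
internal scans; three replicates per depth are emitted to exercise
averaging); PAR σ_spectral/√5. Between-leaf trait variation is
multiplicative log-normal with log-sd calibrated so the CV equals
σ_trait (keeps observables positive at CV 0.25); α and leaf dimensions
use half that CV — quantum yields and geometry vary less than
capacities — and α is capped below 0.95·AF·0.5, the ceiling above
which a fluorescence trace cannot encode the curve. Fluorescence
measurement noise enters as a per-step gain factor common to Fs and
Fm′ plus an independent multiplicative factor on the yield: a common
gain cancels in ΔF/Fm′, whereas independent raw noise on Fs and Fm′
would be amplified without bound at saturating light, where ΔF is a
small difference of large signals. Defaults: σ_spectral = σ_fluoro =
0.05, σ_trait = 0.25.

**What the generator does not emulate.** Upwelling irradiance and
scattering (diffuse attenuation only), epiphyton, hydrodynamics and
within-day light variation, plant-to-plant covariance structure beyond
independent log-normal factors, and any coupling between the spectral
field and the plant gradients (the gradients are imposed, not emergent).
Passing round-trip tests therefore demonstrates that the estimators
invert the stated generating model — not that field data would be this
clean, nor that the gradients causally follow from the light field.

## Problem sizes

The default test and analysis runs use the campaign-sized grids: 351
wavelengths (400–750 nm at 1 nm), nine depths × three replicates,
nine leaf levels, twenty plants (four sites × five), four quadrats.
Stochastic checks use 200 fit replicates and 1000 correlation draws.

## Known limitations

- The Webb model is the only light-response form implemented; Platt or
  Jassby–Platt variants would need a second named model.
- The correlation stage reports unadjusted p-values by design (per-test
  stars, no multiplicity correction).
- `morphometrics_summary` assumes the boxplot conventions used here
  (median, central 75% range, 5th/95th percentiles).
- The scalar PAR model and the spectral field are deliberately
  decoupled (see above); integrating one from the other will not
  reproduce both sets of anchors.
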