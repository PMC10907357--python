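"""Seeded generator of synthetic light fields, plants and fluorescence traces.

Emulates the statistical structure of a shallow-lake field campaign on a
canopy-forming pondweed so that every analysis stage can be exercised,
and its headline quantities recovered, without any field data:

* a layered Beer–Lambert spectral light field — an open-water
  attenuation spectrum (bimodal, calibrated so the PAR half-depth is
  0.60 m and Kd(650)−Kd(750) = 0.0404 m⁻¹, i.e. r/fr falls from 1.0 at
  the surface to 0.98 at 0.5 m) plus a chlorophyll-like canopy
  absorption band spanning 450–650 nm whose strength and vertical
  placement depend on patch density;
* PAR profiles per density class from a scalar attenuation model
  (half-depth 0.60 m open water, 0.50 m low density; in high density
  the top 0.1 m attenuates at ln(3)/0.1 m⁻¹, leaving one third of
  surface PAR at 10 cm);
* a plant with nine leaf levels whose light-response truth declines
  linearly with depth (mean Ik = 160 µmol m⁻² s⁻¹ with a 30% apex→base
  decrease, ETRmax 50.0 → 36.5, a 27% decrease), leaf areas that put
  56% of the potential assimilation ETRmax·LA in the top 40 cm, and
  pigment gradients (total chlorophyll ×2.5 over the top 60 cm,
  chl a/b −25%, chl/car +56% apex→base);
* synthetic PAM induction traces that invert exactly through the
  quenching equations at zero noise.

One integer seed fixes all randomness bit-exactly.  All noise is
multiplicative: log-normal on spectra and traits (traits use a log-sd
calibrated so the coefficient of variation equals the requested sigma),
Gaussian factors on fluorescence yields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fluorometry import DEFAULT_AF, InductionTrace, LightStep, webb_model
from .light_field import (
    CANONICAL_DEPTHS_M,
    ParProfile,
    SpectralField,
    SpectralScan,
    average_replicates,
)
from .traits import CANONICAL_LEAF_LEVELS_CM

__all__ = [
    "Scenario",
    "FieldTruth",
    "PlantTruth",
    "water_kd",
    "canopy_kd",
    "generate_field",
    "generate_plant",
    "simulate_induction",
    "write_scenario_csvs",
    "DEFAULT_IRRADIANCES",
]

#: Actinic step sequence (µmol m⁻² s⁻¹): 11 steps spanning 5–787,
#: geometrically spaced as rapid-light-curve protocols are.
DEFAULT_IRRADIANCES = (5, 8, 14, 23, 38, 63, 104, 173, 287, 476, 787)

# ---------------------------------------------------------------------------
# optical calibration constants
# ---------------------------------------------------------------------------

#: Open-water PAR half-depth (m) and the derived PAR attenuation (m⁻¹).
OPEN_WATER_HALF_DEPTH_M = 0.60
KD_PAR_OPEN = math.log(2.0) / OPEN_WATER_HALF_DEPTH_M

#: Kd(650) − Kd(750) of open water (m⁻¹): −2·ln(0.98), so that with a
#: surface red:far-red ratio of 1.0 the ratio at 0.5 m is 0.98.
RFR_DELTA_OPEN = -2.0 * math.log(0.98)

#: Canopy Kd(650) − Kd(750) inside a high-density canopy layer (m⁻¹);
#: over the 0.2 m canopy this takes r/fr at 0.5 m down to ≈0.46.
RFR_DELTA_HIGH_CANOPY = 3.78

#: Peak total Kd (m⁻¹) inside the 450–650 nm band for a moderate canopy.
PEAK_KD_MODERATE = 3.0

#: High-density canopy occupies the top 0.2 m of the water column.
HIGH_CANOPY_BOTTOM_M = 0.2


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _red_edge(wl: np.ndarray, centre: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp((wl - centre) / width))


def water_kd(wavelengths: np.ndarray) -> np.ndarray:
    """Open-water attenuation spectrum Kd(λ) (m⁻¹).

    Bimodal — absorption peaks in the 400–500 and 600–700 nm bands, as
    humic shallow-lake water shows — with two calibrated integrals: the
    flat-weight mean over 400–700 nm equals ln2/0.6 m⁻¹ (PAR half-depth
    0.60 m) and Kd(650) − Kd(750) = 0.0404 m⁻¹ (open-water r/fr at
    0.5 m = 0.98 for a surface ratio of 1.0).
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl[0] > 400 or wl[-1] < 750:
        raise ValueError("wavelength grid must cover 400–750 nm")
    blue = 0.35 * _gauss(wl, 450.0, 45.0)
    red = 0.30 * _gauss(wl, 700.0, 45.0)  # symmetric about 700: no 650/750 tilt

    def parts(w):
        b = 0.35 * _gauss(w, 450.0, 45.0)
        r = 0.30 * _gauss(w, 700.0, 45.0)
        e = _red_edge(w, 700.0, 25.0)
        return b, r, e

    w650, w750 = np.array([650.0]), np.array([750.0])
    b6, r6, e6 = parts(w650)
    b7, r7, e7 = parts(w750)
    # tilt scale so the full spectrum has exactly the open-water 650−750 step
    d = (RFR_DELTA_OPEN - (b6 - b7) - (r6 - r7)) / (e6 - e7)
    d = float(d[0])

    fine = np.linspace(400.0, 700.0, 1201)  # PAR band, flat weighting
    bf, rf, ef = parts(fine)
    base = KD_PAR_OPEN - float(np.mean(bf + rf + d * ef))
    kd = base + blue + red + d * _red_edge(wl, 700.0, 25.0)
    return kd


def _canopy_shape(wl: np.ndarray) -> np.ndarray:
    """Chlorophyll-like canopy absorption band (unnormalised shape).

    Two broad Gaussians (470 and 620 nm) spanning the 450–650 nm range,
    cut off by a sharp red edge near 700 nm — pigments absorb red light
    but not far-red.
    """
    wl = np.asarray(wl, dtype=float)
    band = _gauss(wl, 470.0, 60.0) + _gauss(wl, 620.0, 70.0)
    return band * _red_edge(wl, 700.0, 10.0)


def _moderate_scale(wavelengths: np.ndarray) -> float:
    """Canopy scale making peak total Kd in 450–650 nm equal 3.0 m⁻¹."""
    wl = np.asarray(wavelengths, dtype=float)
    band = (wl >= 450) & (wl <= 650)
    kw = water_kd(wl)[band]
    s = _canopy_shape(wl)[band]
    # peak of kw + c*s is monotone increasing in c; solve by bisection
    lo, hi = 0.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.max(kw + mid * s) < PEAK_KD_MODERATE:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _high_scale() -> float:
    """Canopy scale giving Kd(650) − Kd(750) = 3.78 m⁻¹ in the canopy layer."""
    s650 = float(_canopy_shape(np.array([650.0]))[0])
    s750 = float(_canopy_shape(np.array([750.0]))[0])
    return RFR_DELTA_HIGH_CANOPY / (s650 - s750)


def canopy_kd(
    density_class: str,
    wavelengths: np.ndarray,
    biomass_weights: list[tuple[float, float, float]] | None = None,
) -> list[tuple[float, float, np.ndarray]]:
    """Added (canopy) attenuation per depth layer.

    Returns ``[(z_top_m, z_bottom_m, kd_added(λ)), ...]``.  Defaults per
    density class: open water and low density add nothing (a sparse
    canopy barely changes the spectrum); a moderate canopy fills the
    water column uniformly, scaled so the peak total Kd in the 450–650
    band is 3.0 m⁻¹; a high-density canopy is concentrated in the top
    0.2 m, scaled so Kd(650) − Kd(750) there is 3.78 m⁻¹ (its in-canopy
    band peak then comes out near 6 m⁻¹).

    ``biomass_weights`` — ``[(z_top, z_bottom, relative_biomass), ...]``
    — replaces the default vertical placement; the class scale then
    multiplies each layer's relative biomass.
    """
    wl = np.asarray(wavelengths, dtype=float)
    shape = _canopy_shape(wl)
    zmax = 10.0  # effectively "to the bottom"
    if density_class in ("open_water", "low"):
        scale, default_w = 0.0, [(0.0, zmax, 1.0)]
    elif density_class == "moderate":
        scale, default_w = _moderate_scale(wl), [(0.0, zmax, 1.0)]
    elif density_class == "high":
        scale, default_w = _high_scale(), [(0.0, HIGH_CANOPY_BOTTOM_M, 1.0)]
    else:
        raise ValueError(f"unknown density class {density_class!r}")
    weights = biomass_weights if biomass_weights is not None else default_w
    return [(zt, zb, scale * w * shape) for zt, zb, w in weights]


# per-class scalar PAR attenuation: [(z_top, z_bottom, kd_par), ...]
def _par_kd_segments(density_class: str) -> list[tuple[float, float, float]]:
    zmax = 10.0
    if density_class == "open_water":
        return [(0.0, zmax, KD_PAR_OPEN)]
    if density_class == "low":
        return [(0.0, zmax, math.log(2.0) / 0.5)]  # half-depth ≈ 0.5 m
    if density_class == "moderate":
        return [(0.0, zmax, KD_PAR_OPEN + 0.8)]
    if density_class == "high":
        # one third of surface PAR left at 10 cm; denser-than-water below
        return [(0.0, 0.1, math.log(3.0) / 0.1), (0.1, zmax, KD_PAR_OPEN + 1.5)]
    raise ValueError(f"unknown density class {density_class!r}")


@dataclass
class Scenario:
    """Study conditions for one synthetic data set.

    The defaults are the campaign's: nine optical depths 0–1.5 m, nine
    leaf levels 1–140 cm, three spectral replicates per depth, four
    harvested quadrats, twenty sampled plants (4 sites × 5 plants).
    """

    density_class: str = "moderate"
    seed: int = 0
    n_plants_m2: float = 15.0
    spectral_sigma: float = 0.05
    fluoro_sigma: float = 0.05
    trait_sigma: float = 0.25
    depths_m: tuple[float, ...] = CANONICAL_DEPTHS_M
    leaf_levels_cm: tuple[float, ...] = CANONICAL_LEAF_LEVELS_CM
    wavelengths_nm: np.ndarray = field(
        default_factory=lambda: np.arange(400.0, 751.0, 1.0)
    )
    n_replicates: int = 3
    n_internal_scans: int = 25  # spectra internally averaged per replicate
    n_plants: int = 20
    n_quadrats: int = 4
    surface_par: float = 1500.0
    site_label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.density_class not in ("open_water", "low", "moderate", "high"):
            raise ValueError(f"unknown density class {self.density_class!r}")
        for name in ("spectral_sigma", "fluoro_sigma", "trait_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def noiseless(self) -> "Scenario":
        return replace(self, spectral_sigma=0.0, fluoro_sigma=0.0, trait_sigma=0.0)


@dataclass
class FieldTruth:
    """Generating optics of a synthetic field."""

    wavelengths_nm: np.ndarray
    water_kd: np.ndarray
    canopy_layers: list[tuple[float, float, np.ndarray]]
    par_kd_segments: list[tuple[float, float, float]]

    def total_kd(self, z_top: float, z_bottom: float) -> np.ndarray:
        """Mean total Kd(λ) over the layer [z_top, z_bottom]."""
        dz = z_bottom - z_top
        kd = self.water_kd.astype(float).copy()
        for zt, zb, add in self.canopy_layers:
            overlap = max(0.0, min(z_bottom, zb) - max(z_top, zt))
            kd = kd + add * (overlap / dz)
        return kd

    def optical_depth(self, z: float) -> np.ndarray:
        tau = self.water_kd * z
        for zt, zb, add in self.canopy_layers:
            tau = tau + add * max(0.0, min(z, zb) - zt)
        return tau


@dataclass
class FieldBundle:
    replicates: list[list[SpectralScan]]  # per depth, n_replicates scans
    field: SpectralField  # replicate-averaged
    par: ParProfile
    truth: FieldTruth


def _lognormal_factor(rng: np.random.Generator, sigma: float, size=None):
    """Multiplicative log-normal noise with coefficient of variation sigma."""
    if sigma == 0:
        return 1.0 if size is None else np.ones(size)
    log_sd = math.sqrt(math.log1p(sigma**2))
    return np.exp(rng.normal(-0.5 * log_sd**2, log_sd, size=size))


def generate_field(scenario: Scenario) -> FieldBundle:
    """Forward Beer–Lambert layering of water plus canopy attenuation.

    Surface spectrum is spectrally flat (relative units; surface r/fr
    exactly 1.0).  Each of the ``n_replicates`` scans per depth carries
    log-normal noise of ``spectral_sigma/√n_internal_scans`` (the
    instrument averages ``n_internal_scans`` spectra per recorded scan);
    PAR readings carry ``spectral_sigma/√5`` (five readings averaged).
    Noiseless and bit-reproducible at ``spectral_sigma = 0``.
    """
    rng = np.random.default_rng(scenario.seed)
    wl = np.asarray(scenario.wavelengths_nm, dtype=float)
    truth = FieldTruth(
        wavelengths_nm=wl,
        water_kd=water_kd(wl),
        canopy_layers=canopy_kd(scenario.density_class, wl),
        par_kd_segments=_par_kd_segments(scenario.density_class),
    )
    ed0 = np.full(wl.shape, 100.0)
    rep_sigma = scenario.spectral_sigma / math.sqrt(scenario.n_internal_scans)

    replicates: list[list[SpectralScan]] = []
    for z in scenario.depths_m:
        ed_true = ed0 * np.exp(-truth.optical_depth(z))
        reps = [
            SpectralScan(z, wl, ed_true * _lognormal_factor(rng, rep_sigma, wl.shape))
            for _ in range(scenario.n_replicates)
        ]
        replicates.append(reps)
    fld = SpectralField(
        scans=[average_replicates(reps) for reps in replicates],
        site_label=scenario.site_label,
        density_class=scenario.density_class,
    )

    par_sigma = scenario.spectral_sigma / math.sqrt(5.0)
    par_vals = []
    for z in scenario.depths_m:
        tau = sum(
            k * max(0.0, min(z, zb) - zt) for zt, zb, k in truth.par_kd_segments
        )
        par_vals.append(
            scenario.surface_par * math.exp(-tau) * float(_lognormal_factor(rng, par_sigma))
        )
    par = ParProfile(np.asarray(scenario.depths_m, float), np.asarray(par_vals))
    return FieldBundle(replicates=replicates, field=fld, par=par, truth=truth)


# ---------------------------------------------------------------------------
# plant truth calibration
# ---------------------------------------------------------------------------

IK_MEAN = 160.0  # whole-plant mean saturation intensity, µmol m⁻² s⁻¹
IK_BASAL_RATIO = 0.70  # 30% apex→base decrease
ETRMAX_APEX = 50.0  # µmol e⁻ m⁻² s⁻¹
ETRMAX_BASE = 36.5  # 27% decrease
LA_APICAL_CM2 = 13.24  # leaf area per level, levels ≤ 40 cm
LA_BASAL_CM2 = 10.0  # deeper levels; puts 56% of ETRmax·LA in the top 40 cm
APICAL_DEPTH_CM = 40.0

FVFM_APEX, FVFM_BASE = 0.70, 0.78  # Fv/Fm rises with depth (less light stress)
TOTAL_CHL_APEX_UG_CM2 = 16.0  # rises 2.5× over the top 60 cm, then flat
CHL_AB_APEX, CHL_AB_BASE = 3.2, 2.4  # −25% apex→base
CHL_CAR_APEX, CHL_CAR_BASE = 4.0, 6.24  # +56% apex→base
LEAF_LENGTH_APEX_CM, LEAF_LENGTH_BASE_CM = 4.8, 5.8

DARK_FM = 1000.0  # arbitrary fluorescence units for synthetic traces


def _linear_gradient(levels_cm: np.ndarray, top: float, bottom: float) -> np.ndarray:
    z0, z1 = levels_cm[0], levels_cm[-1]
    return top + (bottom - top) * (levels_cm - z0) / (z1 - z0)


@dataclass
class PlantTruth:
    """Per-level ground truth of the default plant."""

    levels: pd.DataFrame  # one row per leaf level

    @property
    def apical_share_percent(self) -> float:
        prod = self.levels["etr_max"] * self.levels["la_cm2"]
        top = prod[self.levels["depth_cm"] <= APICAL_DEPTH_CM].sum()
        return 100.0 * top / prod.sum()


def plant_truth(levels_cm=CANONICAL_LEAF_LEVELS_CM) -> PlantTruth:
    """Calibrated per-level truth table.

    The Ik gradient is the exact linear solution of "mean over the nine
    levels = 160 with a basal/apical ratio of 0.70"; ETRmax runs
    linearly 50.0 → 36.5; α is their ratio; leaf area steps from 13.24
    to 10.0 cm² below 40 cm.
    """
    z = np.asarray(levels_cm, dtype=float)
    rel = (z - z[0]) / (z[-1] - z[0])
    ik_apex = IK_MEAN / float(np.mean(1.0 - (1.0 - IK_BASAL_RATIO) * rel))
    ik = ik_apex * (1.0 - (1.0 - IK_BASAL_RATIO) * rel)
    etr_max = _linear_gradient(z, ETRMAX_APEX, ETRMAX_BASE)
    alpha = etr_max / ik
    la = np.where(z <= APICAL_DEPTH_CM, LA_APICAL_CM2, LA_BASAL_CM2)
    fv_fm = _linear_gradient(z, FVFM_APEX, FVFM_BASE)

    total_chl = TOTAL_CHL_APEX_UG_CM2 * (1.0 + 1.5 * np.minimum(z, 60.0) / 60.0)
    chl_ab = _linear_gradient(z, CHL_AB_APEX, CHL_AB_BASE)
    chl_car = _linear_gradient(z, CHL_CAR_APEX, CHL_CAR_BASE)

    length = _linear_gradient(z, LEAF_LENGTH_APEX_CM, LEAF_LENGTH_BASE_CM)
    area = la.astype(float)
    width = 4.0 * area / (math.pi * length)  # ellipse-consistent width
    a, b = length / 2.0, width / 2.0
    perimeter = math.pi * (
        3.0 * (a + b) - np.sqrt((3.0 * a + b) * (a + 3.0 * b))
    )  # Ramanujan
    circularity = 4.0 * math.pi * area / perimeter**2

    return PlantTruth(
        levels=pd.DataFrame(
            {
                "depth_cm": z,
                "etr_max": etr_max,
                "alpha": alpha,
                "i_k": ik,
                "fv_fm": fv_fm,
                "la_cm2": la,
                "total_chl_ug_cm2": total_chl,
                "chl_ab_ratio": chl_ab,
                "chl_car_ratio": chl_car,
                "length_cm": length,
                "width_cm": width,
                "area_cm2": area,
                "perimeter_cm": perimeter,
                "circularity": circularity,
            }
        )
    )


def simulate_induction(
    etr_max: float,
    alpha: float,
    f0: float = 200.0,
    fm: float = DARK_FM,
    irradiances=DEFAULT_IRRADIANCES,
    fluoro_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    leaf_id: str = "",
    depth_cm: float = float("nan"),
    af: float = DEFAULT_AF,
) -> InductionTrace:
    """Synthesise a PAM induction trace whose ETR curve is the Webb model.

    At each step the target ETR(I) fixes the required quantum yield
    y = ETR/(I·AF·0.5); Fm′(I) = Fm/(1 + 0.8·I/(I+300)) is a saturating
    NPQ surrogate and Fs = Fm′·(1 − y).  Measurement noise
    ``fluoro_sigma`` enters as a per-step detector-gain factor common to
    Fs and Fm′ plus an independent multiplicative factor on the quantum
    yield (a common gain cancels in ΔF/Fm′; raw independent noise on Fs
    and Fm′ would blow up without bound in the yield at saturating
    light, where ΔF is a small difference of large signals).  At zero
    noise the trace inverts exactly through the quenching equations, so
    curve fitting recovers (ETRmax, α) to optimizer precision.
    """
    if etr_max <= 0 or alpha <= 0:
        raise ValueError("etr_max and alpha must be > 0")
    if rng is None:
        rng = np.random.default_rng(0)
    steps = []
    for k, i in enumerate(irradiances):
        target = float(webb_model(np.array([i]), etr_max, alpha)[0])
        y = target / (i * af * 0.5)
        if y > 1:
            raise ValueError(
                f"step {k + 1} (I={i}): required yield {y:.3f} > 1 — "
                f"ETR {target:.1f} unreachable at this irradiance"
            )
        fm_prime = fm / (1.0 + 0.8 * i / (i + 300.0))
        if fluoro_sigma > 0:
            gain = 1.0 + fluoro_sigma * rng.standard_normal()
            y_obs = y * (1.0 + fluoro_sigma * rng.standard_normal())
            fm_prime *= max(gain, 0.05)
            fs = max(fm_prime * (1.0 - y_obs), 0.0)
        else:
            fs = fm_prime * (1.0 - y)
        steps.append(LightStep(i=float(i), fs=fs, fm_prime=fm_prime))
    return InductionTrace(f0=f0, fm=fm, steps=steps, leaf_id=leaf_id, depth_cm=depth_cm)


# per-class vertical biomass truth over the canonical harvest layers
# (g m⁻³ total, leaf fraction); qualitative shapes: uniform ≈270 g m⁻³ at
# low density, bimodal ≈800 surface / ≈1000 basal at high density.
_BIOMASS_TRUTH = {
    "low": (
        [270.0] * 9,
        [0.20] * 9,
    ),
    "moderate": (
        [400.0, 350.0, 300.0, 300.0, 300.0, 350.0, 400.0, 450.0, 500.0],
        [0.25, 0.22, 0.18, 0.15, 0.12, 0.10, 0.10, 0.10, 0.10],
    ),
    "high": (
        [800.0, 500.0, 400.0, 350.0, 350.0, 400.0, 500.0, 700.0, 1000.0],
        [0.30, 0.25, 0.15, 0.10, 0.08, 0.06, 0.05, 0.05, 0.05],
    ),
}
_HARVEST_LAYERS_CM = (
    (0, 10), (10, 30), (30, 50), (50, 70), (70, 90),
    (90, 110), (110, 130), (130, 150), (150, 170),
)
LEAF_AREA_PER_G_CM2 = 20.8  # dry leaf area:weight; puts peak LAI near 5000 cm² m⁻³

DISC_DIAMETER_CM = 1.0
EXTRACT_VOLUME_ML = 5.0

# inverse of the Lichtenthaler 80%-acetone equations (µg ml⁻¹ → absorbance)
_PIGMENT_DET = 12.25 * 21.50 - 2.79 * 5.10


def _absorbances_from_concentrations(chl_a: float, chl_b: float, car: float):
    a663 = (21.50 * chl_a + 2.79 * chl_b) / _PIGMENT_DET
    a646 = (5.10 * chl_a + 12.25 * chl_b) / _PIGMENT_DET
    a470 = (198.0 * car + 1.82 * chl_a + 85.02 * chl_b) / 1000.0
    return a663, a646, a470


@dataclass
class PlantBundle:
    truth: PlantTruth
    leaf_truth: pd.DataFrame  # per sampled leaf: noisy generating parameters
    fluoro: pd.DataFrame  # fluoro.csv shape
    pigments: pd.DataFrame  # pigments.csv shape
    morpho: pd.DataFrame  # morpho.csv shape
    biomass: pd.DataFrame  # biomass.csv shape
    traces: list[InductionTrace]


def generate_plant(scenario: Scenario) -> PlantBundle:
    """Sampled plants around the calibrated truth, as analysis-ready tables.

    Each of ``n_plants`` plants carries one leaf per level; leaf-level
    observables are the truth times log-normal factors with CV
    ``trait_sigma`` (α and the morphometric dimensions use half that CV
    — quantum yields and leaf geometry vary less between leaves than
    capacities do — and α is additionally kept below 0.95·AF·0.5, the
    ceiling above which a fluorescence trace cannot encode the curve).
    Fluorescence traces per leaf carry ``fluoro_sigma`` measurement
    noise on top.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    truth = plant_truth(scenario.leaf_levels_cm)
    tl = truth.levels
    sig, half = scenario.trait_sigma, scenario.trait_sigma / 2.0

    leaf_rows, fluoro_rows, pig_rows, morpho_rows, traces = [], [], [], [], []
    disc_area = math.pi * (DISC_DIAMETER_CM / 2.0) ** 2
    alpha_cap = 0.95 * DEFAULT_AF * 0.5
    for p in range(1, scenario.n_plants + 1):
        for _, lv in tl.iterrows():
            leaf_id = f"p{p:02d}_d{int(lv.depth_cm):03d}"
            em = float(lv.etr_max * _lognormal_factor(rng, sig))
            al = min(float(lv.alpha * _lognormal_factor(rng, half)), alpha_cap)
            fvfm = min(float(lv.fv_fm * _lognormal_factor(rng, half / 2.0)), 0.85)
            f0 = DARK_FM * (1.0 - fvfm)
            la = float(lv.la_cm2 * _lognormal_factor(rng, sig))

            trace = simulate_induction(
                em, al, f0=f0, fm=DARK_FM,
                fluoro_sigma=scenario.fluoro_sigma, rng=rng,
                leaf_id=leaf_id, depth_cm=float(lv.depth_cm),
            )
            traces.append(trace)
            fluoro_rows.append(
                {
                    "leaf_id": leaf_id, "site": scenario.site_label,
                    "depth_cm": lv.depth_cm, "record_type": "dark",
                    "i_umol_m2_s": 0.0, "f0": f0, "fm": DARK_FM,
                    "fs": np.nan, "fm_prime": np.nan, "f0_prime": np.nan,
                }
            )
            for s in trace.steps:
                fluoro_rows.append(
                    {
                        "leaf_id": leaf_id, "site": scenario.site_label,
                        "depth_cm": lv.depth_cm, "record_type": "step",
                        "i_umol_m2_s": s.i, "f0": np.nan, "fm": np.nan,
                        "fs": s.fs, "fm_prime": s.fm_prime, "f0_prime": np.nan,
                    }
                )

            t_chl = float(lv.total_chl_ug_cm2 * _lognormal_factor(rng, sig))
            r_ab = float(lv.chl_ab_ratio * _lognormal_factor(rng, half))
            r_car = float(lv.chl_car_ratio * _lognormal_factor(rng, half))
            chl_a_area = t_chl * r_ab / (1.0 + r_ab)
            chl_b_area = t_chl / (1.0 + r_ab)
            car_area = t_chl / r_car
            per_ml = disc_area / EXTRACT_VOLUME_ML
            a663, a646, a470 = _absorbances_from_concentrations(
                chl_a_area * per_ml, chl_b_area * per_ml, car_area * per_ml
            )
            pig_rows.append(
                {
                    "leaf_id": leaf_id, "depth_cm": lv.depth_cm,
                    "a663_2": a663, "a646_8": a646, "a470": a470,
                    "extract_ml": EXTRACT_VOLUME_ML,
                    "disc_diameter_cm": DISC_DIAMETER_CM,
                }
            )

            length = float(lv.length_cm * _lognormal_factor(rng, half))
            area = la  # scanned area is the level leaf area observable
            width = 4.0 * area / (math.pi * length)
            a_ax, b_ax = length / 2.0, width / 2.0
            perim = math.pi * (
                3.0 * (a_ax + b_ax)
                - math.sqrt((3.0 * a_ax + b_ax) * (a_ax + 3.0 * b_ax))
            )
            morpho_rows.append(
                {
                    "leaf_id": leaf_id, "depth_cm": lv.depth_cm,
                    "length_cm": length, "width_cm": width, "area_cm2": area,
                    "perimeter_cm": perim,
                    "circularity": 4.0 * math.pi * area / perim**2,
                }
            )
            leaf_rows.append(
                {
                    "leaf_id": leaf_id, "plant": p, "depth_cm": lv.depth_cm,
                    "etr_max": em, "alpha": al, "i_k": em / al,
                    "fv_fm": fvfm, "la_cm2": la,
                }
            )

    bio_rows = []
    if scenario.density_class != "open_water":
        totals, leaf_fracs = _BIOMASS_TRUTH[scenario.density_class]
        for q in range(1, scenario.n_quadrats + 1):
            for (top, bottom), tot, lf in zip(_HARVEST_LAYERS_CM, totals, leaf_fracs):
                h = (bottom - top) / 100.0
                total_g = tot * 0.25 * h * float(_lognormal_factor(rng, sig))
                leaf_g = total_g * min(lf * float(_lognormal_factor(rng, half)), 0.95)
                bio_rows.append(
                    {
                        "site": f"{scenario.site_label}_q{q}",
                        "density_class": scenario.density_class,
                        "layer_top_cm": top, "layer_bottom_cm": bottom,
                        "quadrat_m2": 0.25, "total_dry_g": total_g,
                        "leaf_dry_g": leaf_g,
                        "leaf_area_cm2": leaf_g * LEAF_AREA_PER_G_CM2,
                    }
                )

    return PlantBundle(
        truth=truth,
        leaf_truth=pd.DataFrame(leaf_rows),
        fluoro=pd.DataFrame(fluoro_rows),
        pigments=pd.DataFrame(pig_rows),
        morpho=pd.DataFrame(morpho_rows),
        biomass=pd.DataFrame(bio_rows),
        traces=traces,
    )


def write_scenario_csvs(scenario: Scenario, outdir) -> dict[str, str]:
    """Write the full CSV suite for one scenario; returns name → path.

    Files: spectra.csv, par.csv, fluoro.csv, pigments.csv, biomass.csv,
    morpho.csv and truth.csv (long-format generating truth).
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fb = generate_field(scenario)
    pb = generate_plant(scenario)

    spec_rows = []
    for reps in fb.replicates:
        for r, scan in enumerate(reps, start=1):
            spec_rows.append(
                pd.DataFrame(
                    {
                        "site": scenario.site_label,
                        "density_class": scenario.density_class,
                        "replicate": r,
                        "depth_cm": round(scan.depth_m * 100.0, 6),
                        "wavelength_nm": scan.wavelengths_nm,
                        "ed": scan.ed,
                    }
                )
            )
    spectra = pd.concat(spec_rows, ignore_index=True)
    par = pd.DataFrame(
        {
            "site": scenario.site_label,
            "density_class": scenario.density_class,
            "depth_cm": np.round(fb.par.depths_m * 100.0, 6),
            "par_umol_m2_s": fb.par.par,
        }
    )

    truth_rows = [
        {"section": "water_kd", "key": f"{w:.1f}", "value": v}
        for w, v in zip(fb.truth.wavelengths_nm, fb.truth.water_kd)
    ]
    for zt, zb, add in fb.truth.canopy_layers:
        truth_rows += [
            {"section": f"canopy_kd_{zt}_{zb}", "key": f"{w:.1f}", "value": v}
            for w, v in zip(fb.truth.wavelengths_nm, add)
        ]
    for _, lv in pb.truth.levels.iterrows():
        for col in pb.truth.levels.columns:
            if col != "depth_cm":
                truth_rows.append(
                    {
                        "section": "plant_level",
                        "key": f"{col}@{int(lv.depth_cm)}",
                        "value": lv[col],
                    }
                )
    truth = pd.DataFrame(truth_rows)

    paths = {}
    for name, df in [
        ("spectra", spectra), ("par", par), ("fluoro", pb.fluoro),
        ("pigments", pb.pigments), ("biomass", pb.biomass),
        ("morpho", pb.morpho), ("truth", truth),
    ]:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = str(path)
    return paths
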