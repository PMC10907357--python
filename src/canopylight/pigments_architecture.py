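"""Leaf pigments from extract absorbances; canopy layers from harvests.

Two bookkeeping halves of the field campaign:

* pigment concentrations (chlorophyll a, b, carotenoids) from the
  absorbances of an 80%-acetone extract of a leaf disc, via the
  Lichtenthaler empirical equations, reported both per ml of extract
  and per cm² of leaf;
* per-depth-layer canopy accounting — harvested 20 cm plant segments
  converted to volumetric biomass density (g m⁻³), assimilatory biomass
  ratio (leaf mass as % of total), and a volumetric leaf-area index
  LAI_d (cm² m⁻³) — plus leaf-shape summaries of scanned leaves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PigmentSample",
    "PigmentResult",
    "LayerRecord",
    "EQUATION_SETS",
    "pigment_concentrations",
    "volumetric_density",
    "assimilatory_ratio",
    "leaf_area_to_weight",
    "circularity_index",
    "morphometrics_summary",
]

#: Area of the standard 1-cm-diameter leaf disc (cm²).
DEFAULT_DISC_AREA_CM2 = math.pi * 0.5**2

#: Canonical 20-cm harvest layers (top_cm, bottom_cm); the apical layer is 10 cm.
CANONICAL_LAYERS_CM = (
    (0, 10), (10, 30), (30, 50), (50, 70), (70, 90),
    (90, 110), (110, 130), (130, 150), (150, 170),
)


@dataclass(frozen=True)
class PigmentSample:
    """Absorbances of one leaf-disc extract (80% acetone, 1 cm path)."""

    a663_2: float
    a646_8: float
    a470: float
    extract_volume_ml: float = 5.0
    disc_area_cm2: float = DEFAULT_DISC_AREA_CM2
    depth_cm: float = float("nan")
    leaf_id: str = ""

    def __post_init__(self) -> None:
        if min(self.a663_2, self.a646_8, self.a470) < 0:
            raise ValueError("absorbances must be >= 0")
        if self.disc_area_cm2 <= 0 or self.extract_volume_ml <= 0:
            raise ValueError("disc area and extract volume must be > 0")


@dataclass
class PigmentResult:
    """Pigment concentrations per ml extract and per cm² leaf, with ratios."""

    chl_a_ug_ml: float
    chl_b_ug_ml: float
    car_ug_ml: float
    chl_a_ug_cm2: float
    chl_b_ug_cm2: float
    car_ug_cm2: float
    flagged: bool = False  # any negative concentration (turbid extract)

    @property
    def total_chl_ug_ml(self) -> float:
        return self.chl_a_ug_ml + self.chl_b_ug_ml

    @property
    def total_chl_ug_cm2(self) -> float:
        return self.chl_a_ug_cm2 + self.chl_b_ug_cm2

    @property
    def chl_ab_ratio(self) -> float:
        return self.chl_a_ug_ml / self.chl_b_ug_ml if self.chl_b_ug_ml > 0 else float("nan")

    @property
    def chl_car_ratio(self) -> float:
        return self.total_chl_ug_ml / self.car_ug_ml if self.car_ug_ml > 0 else float("nan")


def _lichtenthaler_80_acetone(a663_2: float, a646_8: float, a470: float):
    chl_a = 12.25 * a663_2 - 2.79 * a646_8
    chl_b = 21.50 * a646_8 - 5.10 * a663_2
    car = (1000.0 * a470 - 1.82 * chl_a - 85.02 * chl_b) / 198.0
    return chl_a, chl_b, car


#: Named empirical equation sets mapping extract absorbances → µg ml⁻¹.
EQUATION_SETS = {"lichtenthaler_80_acetone": _lichtenthaler_80_acetone}


def pigment_concentrations(
    sample: PigmentSample, equation_set: str = "lichtenthaler_80_acetone"
) -> PigmentResult:
    """Pigment concentrations from extract absorbances.

    Per-ml values come straight from the chosen equation set; per-area
    values scale by extract volume over disc area.  Negative computed
    concentrations are kept (they diagnose turbid extracts) but flagged.
    """
    try:
        eqs = EQUATION_SETS[equation_set]
    except KeyError:
        raise ValueError(
            f"unknown equation set {equation_set!r}; known: {sorted(EQUATION_SETS)}"
        ) from None
    chl_a, chl_b, car = eqs(sample.a663_2, sample.a646_8, sample.a470)
    per_area = sample.extract_volume_ml / sample.disc_area_cm2
    return PigmentResult(
        chl_a_ug_ml=chl_a,
        chl_b_ug_ml=chl_b,
        car_ug_ml=car,
        chl_a_ug_cm2=chl_a * per_area,
        chl_b_ug_cm2=chl_b * per_area,
        car_ug_cm2=car * per_area,
        flagged=min(chl_a, chl_b, car) < 0,
    )


@dataclass(frozen=True)
class LayerRecord:
    """One harvested depth layer of a quadrat: masses, leaf area, geometry."""

    layer: tuple[float, float]  # (top_cm, bottom_cm)
    total_dry_g: float
    leaf_dry_g: float
    leaf_area_cm2: float
    quadrat_area_m2: float = 0.25
    n_plants: int | None = None

    def __post_init__(self) -> None:
        top, bottom = self.layer
        if bottom <= top:
            raise ValueError(f"layer requires top < bottom, got {self.layer}")
        height = round((bottom - top) / 100.0, 6)
        if height not in (0.1, 0.2):
            raise ValueError(f"layer height must be 0.1 or 0.2 m, got {height} m")
        if self.leaf_dry_g > self.total_dry_g:
            raise ValueError("leaf mass cannot exceed total mass")
        if self.quadrat_area_m2 <= 0:
            raise ValueError("quadrat area must be > 0")

    @property
    def height_m(self) -> float:
        return (self.layer[1] - self.layer[0]) / 100.0


def volumetric_density(layer: LayerRecord, layer_height_m: float | None = None):
    """Volumetric canopy densities for one layer.

    Masses and leaf area are normalised to 1 m² of bottom and divided by
    the layer height (0.1 m apical, 0.2 m otherwise) — i.e. per m³ of
    the water layer.  ``layer_height_m`` overrides the nominal height
    when the apical segment was harvested longer than 10 cm.

    Returns a dict with ``total_g_m3``, ``leaf_g_m3`` and ``lai_cm2_m3``.
    """
    h = layer.height_m if layer_height_m is None else layer_height_m
    if h <= 0:
        raise ValueError("layer height must be > 0")
    vol = layer.quadrat_area_m2 * h  # m³ sampled
    return {
        "total_g_m3": layer.total_dry_g / vol,
        "leaf_g_m3": layer.leaf_dry_g / vol,
        "lai_cm2_m3": layer.leaf_area_cm2 / vol,
    }


def assimilatory_ratio(layer: LayerRecord) -> float:
    """Leaf dry mass as a percent of total dry mass; NaN for an empty layer."""
    if layer.total_dry_g <= 0:
        return float("nan")
    return 100.0 * layer.leaf_dry_g / layer.total_dry_g


def leaf_area_to_weight(area_cm2: float, dry_g: float) -> float:
    """Leaf area to dry weight ratio (cm² g⁻¹); NaN when mass is not positive."""
    if dry_g <= 0:
        return float("nan")
    return area_cm2 / dry_g


def circularity_index(area_cm2: float, perimeter_cm: float) -> float:
    """Shape index 4π·area/perimeter²: 1 for a circle, → 0 when elongated."""
    if perimeter_cm <= 0:
        return float("nan")
    return 4.0 * math.pi * area_cm2 / perimeter_cm**2


MORPHO_TRAITS = ("length_cm", "width_cm", "area_cm2", "perimeter_cm", "circularity")


def morphometrics_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Boxplot statistics of leaf morphometrics per depth.

    For each depth and each trait present: median, the central 75% range
    (12.5th–87.5th percentiles) and the 5th/95th percentiles.  Expects a
    ``depth_cm`` column; circularity, if present, must lie in [0, 1].
    """
    if "depth_cm" not in records.columns:
        raise ValueError("records need a depth_cm column")
    if "circularity" in records.columns:
        circ = records["circularity"].dropna()
        if ((circ < 0) | (circ > 1)).any():
            raise ValueError("circularity must lie in [0, 1]")
    traits = [c for c in MORPHO_TRAITS if c in records.columns]
    out = []
    for (depth,), grp in records.groupby(["depth_cm"]):
        for t in traits:
            vals = grp[t].dropna().to_numpy()
            if vals.size == 0:
                continue
            q = np.percentile(vals, [5, 12.5, 50, 87.5, 95])
            out.append(
                {
                    "depth_cm": depth,
                    "trait": t,
                    "n": vals.size,
                    "median": q[2],
                    "p12_5": q[1],
                    "p87_5": q[3],
                    "p5": q[0],
                    "p95": q[4],
                }
            )
    return pd.DataFrame(out)
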