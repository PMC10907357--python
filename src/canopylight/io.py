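"""CSV schemas, validation and readers for the analysis tables.

All files are UTF-8, comma-separated, "." decimal, header row mandatory.
Depths are stored in centimetres in files (matching field notebooks) and
converted to metres at this boundary; everything downstream works in
metres.  Extra columns are accepted with a notice; missing required
columns, wrong types and out-of-range values are itemized violations.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .fluorometry import InductionTrace, LightStep
from .light_field import ParProfile, SpectralField, SpectralScan, average_replicates
from .pigments_architecture import LayerRecord, PigmentSample

__all__ = ["SCHEMAS", "SchemaReport", "validate_schema", "read_spectra",
           "read_par", "read_fluoro", "read_pigments", "read_biomass",
           "read_morpho"]


# column -> (kind, (min, max) or None, required); kind "num" or "str"
SCHEMAS: dict[str, dict[str, tuple[str, tuple[float, float] | None, bool]]] = {
    "spectra": {
        "site": ("str", None, True),
        "density_class": ("str", None, True),
        "replicate": ("num", (1, 1000), True),
        "depth_cm": ("num", (0, 200), True),
        "wavelength_nm": ("num", (200, 1100), True),
        "ed": ("num", (0, np.inf), True),
    },
    "par": {
        "site": ("str", None, True),
        "density_class": ("str", None, True),
        "depth_cm": ("num", (0, 200), True),
        "par_umol_m2_s": ("num", (0, 5000), True),
    },
    "fluoro": {
        "leaf_id": ("str", None, True),
        "site": ("str", None, False),
        "depth_cm": ("num", (0, 200), True),
        "record_type": ("str", None, True),
        "i_umol_m2_s": ("num", (0, 5000), True),
        "f0": ("num", (0, np.inf), False),
        "fm": ("num", (0, np.inf), False),
        "fs": ("num", (0, np.inf), False),
        "fm_prime": ("num", (0, np.inf), False),
        "f0_prime": ("num", (0, np.inf), False),
    },
    "pigments": {
        "leaf_id": ("str", None, True),
        "depth_cm": ("num", (0, 200), True),
        "a663_2": ("num", (0, 10), True),
        "a646_8": ("num", (0, 10), True),
        "a470": ("num", (0, 10), True),
        "extract_ml": ("num", (0, 1000), True),
        "disc_diameter_cm": ("num", (0, 50), True),
    },
    "biomass": {
        "site": ("str", None, True),
        "density_class": ("str", None, True),
        "layer_top_cm": ("num", (0, 200), True),
        "layer_bottom_cm": ("num", (0, 200), True),
        "quadrat_m2": ("num", (0, 100), True),
        "total_dry_g": ("num", (0, np.inf), True),
        "leaf_dry_g": ("num", (0, np.inf), True),
        "leaf_area_cm2": ("num", (0, np.inf), True),
    },
    "morpho": {
        "leaf_id": ("str", None, True),
        "depth_cm": ("num", (0, 200), True),
        "length_cm": ("num", (0, 100), True),
        "width_cm": ("num", (0, 100), True),
        "area_cm2": ("num", (0, 10000), True),
        "perimeter_cm": ("num", (0, 1000), True),
        "circularity": ("num", (0, 1), True),
    },
}


@dataclass
class SchemaReport:
    """Outcome of validating one CSV against a named schema."""

    path: str
    schema: str
    ok: bool
    errors: list[str] = dc_field(default_factory=list)
    notices: list[str] = dc_field(default_factory=list)

    def __str__(self) -> str:
        status = "OK" if self.ok else "FAIL"
        lines = [f"[{status}] {self.path} against schema '{self.schema}'"]
        lines += [f"  error: {e}" for e in self.errors]
        lines += [f"  notice: {n}" for n in self.notices]
        return "\n".join(lines)


def validate_schema(path: str | Path, schema_name: str) -> SchemaReport:
    """Column presence, type and unit-range checks for one CSV file."""
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    report = SchemaReport(path=str(path), schema=schema_name, ok=True)
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        report.ok = False
        report.errors.append(f"unreadable file: {exc}")
        return report

    for col, (kind, rng, required) in schema.items():
        if col not in df.columns:
            if required:
                report.ok = False
                report.errors.append(f"missing required column '{col}'")
            continue
        if kind == "num":
            vals = pd.to_numeric(df[col], errors="coerce")
            bad_type = df[col].notna() & vals.isna()
            if bad_type.any():
                report.ok = False
                report.errors.append(
                    f"column '{col}': {int(bad_type.sum())} non-numeric value(s)"
                )
                continue
            if rng is not None:
                lo, hi = rng
                out = vals.dropna()
                n_out = int(((out < lo) | (out > hi)).sum())
                if n_out:
                    report.ok = False
                    report.errors.append(
                        f"column '{col}': {n_out} value(s) outside [{lo}, {hi}]"
                    )
    extra = [c for c in df.columns if c not in schema]
    if extra:
        report.notices.append(f"extra columns accepted: {extra}")
    return report


def _require_valid(path, schema_name) -> pd.DataFrame:
    rep = validate_schema(path, schema_name)
    if not rep.ok:
        raise ValueError(str(rep))
    return pd.read_csv(path)


def read_spectra(path: str | Path) -> dict[tuple[str, str], SpectralField]:
    """Load spectra.csv → one replicate-averaged SpectralField per
    (site, density_class)."""
    df = _require_valid(path, "spectra")
    fields = {}
    for (site, dclass), grp in df.groupby(["site", "density_class"]):
        scans = []
        for depth_cm, dgrp in sorted(grp.groupby("depth_cm"), key=lambda kv: kv[0]):
            reps = []
            for _, rgrp in dgrp.groupby("replicate"):
                rgrp = rgrp.sort_values("wavelength_nm")
                reps.append(
                    SpectralScan(
                        depth_m=depth_cm / 100.0,
                        wavelengths_nm=rgrp["wavelength_nm"].to_numpy(float),
                        ed=rgrp["ed"].to_numpy(float),
                    )
                )
            scans.append(average_replicates(reps))
        fields[(site, dclass)] = SpectralField(
            scans=scans, site_label=site, density_class=dclass
        )
    return fields


def read_par(path: str | Path) -> dict[tuple[str, str], ParProfile]:
    df = _require_valid(path, "par")
    out = {}
    for (site, dclass), grp in df.groupby(["site", "density_class"]):
        grp = grp.sort_values("depth_cm")
        out[(site, dclass)] = ParProfile(
            depths_m=grp["depth_cm"].to_numpy(float) / 100.0,
            par=grp["par_umol_m2_s"].to_numpy(float),
        )
    return out


def read_fluoro(path: str | Path) -> list[InductionTrace]:
    """Load fluoro.csv → one InductionTrace per leaf_id.

    Each leaf needs exactly one 'dark' record (F0, Fm) and its 'step'
    records ordered by irradiance.  Leaves with a malformed dark record
    raise with the leaf named.
    """
    df = _require_valid(path, "fluoro")
    traces = []
    for leaf_id, grp in df.groupby("leaf_id", sort=False):
        dark = grp[grp["record_type"] == "dark"]
        if len(dark) != 1:
            raise ValueError(f"leaf {leaf_id!r}: need exactly one dark record")
        steps_df = grp[grp["record_type"] == "step"].sort_values("i_umol_m2_s")
        steps = [
            LightStep(
                i=float(r.i_umol_m2_s),
                fs=float(r.fs) if pd.notna(r.fs) else float("nan"),
                fm_prime=float(r.fm_prime) if pd.notna(r.fm_prime) else float("nan"),
                f0_prime=float(r.f0_prime) if pd.notna(r.f0_prime) else None,
            )
            for r in steps_df.itertuples()
        ]
        d = dark.iloc[0]
        traces.append(
            InductionTrace(
                f0=float(d["f0"]),
                fm=float(d["fm"]),
                steps=steps,
                leaf_id=str(leaf_id),
                depth_cm=float(d["depth_cm"]),
            )
        )
    return traces


def read_pigments(path: str | Path) -> list[PigmentSample]:
    df = _require_valid(path, "pigments")
    return [
        PigmentSample(
            a663_2=float(r.a663_2),
            a646_8=float(r.a646_8),
            a470=float(r.a470),
            extract_volume_ml=float(r.extract_ml),
            disc_area_cm2=float(np.pi * (r.disc_diameter_cm / 2.0) ** 2),
            depth_cm=float(r.depth_cm),
            leaf_id=str(r.leaf_id),
        )
        for r in df.itertuples()
    ]


def read_biomass(path: str | Path) -> list[tuple[str, str, LayerRecord]]:
    df = _require_valid(path, "biomass")
    out = []
    for r in df.itertuples():
        out.append(
            (
                str(r.site),
                str(r.density_class),
                LayerRecord(
                    layer=(float(r.layer_top_cm), float(r.layer_bottom_cm)),
                    total_dry_g=float(r.total_dry_g),
                    leaf_dry_g=float(r.leaf_dry_g),
                    leaf_area_cm2=float(r.leaf_area_cm2),
                    quadrat_area_m2=float(r.quadrat_m2),
                ),
            )
        )
    return out


def read_morpho(path: str | Path) -> pd.DataFrame:
    return _require_valid(path, "morpho")
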