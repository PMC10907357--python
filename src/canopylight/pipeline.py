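"""End-to-end analysis pipeline.

Joins the stages in the order the campaign's analysis runs them:
spectra → Kd and r/fr profiles; PAR → absorption summaries; induction
records → quenching parameters and light-curve fits; absorbances →
pigments; harvests → layer densities; then the synthesis — trait
matrix, assimilation distribution, CV profiles, trait–environment
correlations and PCA.  The pipeline is a pure function of its input
files and configuration: reruns are byte-identical, every excluded
record is logged with a reason, and a config hash ties outputs to the
run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as cio
from .fluorometry import process_trace
from .light_field import fraction_absorbed, kd_regression, light_level_depth, rfr_profile
from .pigments_architecture import (
    assimilatory_ratio,
    morphometrics_summary,
    pigment_concentrations,
    volumetric_density,
)
from .traits import (
    apical_share,
    correlate_traits,
    pca_traits,
    potential_assimilation,
    trait_cv,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "build_trait_matrix"]


class PipelineError(RuntimeError):
    """Raised before any computation when inputs fail schema validation."""


@dataclass
class PipelineConfig:
    """Input paths plus the knobs the analysis exposes."""

    spectra: str | None = None
    par: str | None = None
    fluoro: str | None = None
    pigments: str | None = None
    biomass: str | None = None
    morpho: str | None = None
    out_dir: str = "results"
    equation_set: str = "lichtenthaler_80_acetone"
    light_curve_model: str = "webb"
    af: float = 0.84
    top_depth_cm: float = 40.0
    mask_negative_kd: bool = False
    strict: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.af <= 1:
            raise ValueError(f"AF must be in (0, 1], got {self.af}")
        if self.light_curve_model != "webb":
            raise ValueError(f"unknown light-curve model {self.light_curve_model!r}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunLog:
    lines: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    exclusions: list[str] = field(default_factory=list)

    def info(self, msg: str) -> None:
        self.lines.append(msg)

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)
        self.lines.append(f"WARNING: {msg}")

    def exclude(self, record: str, reason_code: str, detail: str = "") -> None:
        msg = f"EXCLUDED {record} [{reason_code}] {detail}".rstrip()
        self.exclusions.append(msg)
        self.lines.append(msg)


def _loglinear_env(par_profile, depth_m: float) -> float:
    """PAR at an arbitrary depth, log-linear in the profile."""
    z, p = par_profile.depths_m, par_profile.par
    if depth_m <= z[0]:
        return float(p[0])
    if depth_m >= z[-1]:
        return float(p[-1])
    return float(np.exp(np.interp(depth_m, z, np.log(p))))


def build_trait_matrix(
    light_curves: pd.DataFrame,
    fluoro_params: pd.DataFrame | None = None,
    pigment_results: pd.DataFrame | None = None,
    morpho: pd.DataFrame | None = None,
    rfr: pd.DataFrame | None = None,
    par: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble leaf-level and depth-mean trait matrices.

    Rows are leaves (keyed by leaf_id, depth_cm); trait columns are the
    fitted light-curve parameters, per-leaf mean qP/qN over the light
    steps, Fv/Fm, leaf morphometrics and pigment summaries.  Environment
    columns (depth, PAR interpolated log-linearly, r/fr linearly) are
    attached per depth.  Returns ``(leaf_level, depth_means)``.
    """
    mat = light_curves.copy()
    if fluoro_params is not None and not fluoro_params.empty:
        per_leaf = (
            fluoro_params.groupby("leaf_id")
            .agg(qp=("qp", "mean"), qn=("qn", "mean"), fv_fm=("fv_fm", "first"))
            .reset_index()
        )
        mat = mat.merge(per_leaf, on="leaf_id", how="left")
    if pigment_results is not None and not pigment_results.empty:
        cols = ["leaf_id", "total_chl_ug_cm2", "chl_ab_ratio", "chl_car_ratio"]
        mat = mat.merge(pigment_results[cols], on="leaf_id", how="left")
    if morpho is not None and not morpho.empty:
        cols = [
            c
            for c in ("leaf_id", "length_cm", "width_cm", "area_cm2",
                      "perimeter_cm", "circularity")
            if c in morpho.columns
        ]
        mat = mat.merge(morpho[cols], on="leaf_id", how="left")

    if par is not None and not par.empty:
        zp = par.sort_values("depth_cm")
        z = zp["depth_cm"].to_numpy(float)
        p = zp["par_umol_m2_s"].to_numpy(float)
        with np.errstate(divide="ignore"):
            mat["par_umol_m2_s"] = np.exp(
                np.interp(mat["depth_cm"].to_numpy(float), z, np.log(p))
            )
    if rfr is not None and not rfr.empty:
        zr = rfr.sort_values("depth_cm")
        mat["rfr"] = np.interp(
            mat["depth_cm"].to_numpy(float),
            zr["depth_cm"].to_numpy(float),
            zr["rfr"].to_numpy(float),
        )

    numeric = [c for c in mat.columns if pd.api.types.is_numeric_dtype(mat[c])]
    depth_means = mat.groupby("depth_cm", as_index=False)[
        [c for c in numeric if c != "depth_cm"]
    ].mean()
    return mat, depth_means


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every stage for which inputs were supplied; write output CSVs
    plus run.log under ``config.out_dir``; return the tables by name."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    log.info(f"canopylight {__version__} pipeline, config hash {config.config_hash()}")
    log.info(f"config: {json.dumps(asdict(config), sort_keys=True)}")

    inputs = {
        name: getattr(config, name)
        for name in ("spectra", "par", "fluoro", "pigments", "biomass", "morpho")
        if getattr(config, name) is not None
    }
    reports = {name: cio.validate_schema(path, name) for name, path in inputs.items()}
    bad = [str(r) for r in reports.values() if not r.ok]
    if bad:
        raise PipelineError("schema validation failed:\n" + "\n".join(bad))
    for r in reports.values():
        for n in r.notices:
            log.info(f"{r.path}: {n}")

    tables: dict[str, pd.DataFrame] = {}

    # --- optics ---------------------------------------------------------
    rfr_df = par_df = None
    if "spectra" in inputs:
        fields = cio.read_spectra(inputs["spectra"])
        kd_rows, rfr_rows = [], []
        for (site, dclass), fld in fields.items():
            ks = kd_regression(fld)
            kd = ks.kd.copy()
            if config.mask_negative_kd:
                n_neg = int(np.sum(kd[np.isfinite(kd)] < 0))
                if n_neg:
                    log.warn(f"{site}/{dclass}: masked {n_neg} negative Kd value(s)")
                kd[kd < 0] = np.nan
            kd_rows.append(
                pd.DataFrame(
                    {
                        "site": site,
                        "density_class": dclass,
                        "wavelength_nm": ks.wavelengths_nm,
                        "kd_per_m": kd,
                        "layer_top_cm": ks.layer[0] * 100.0,
                        "layer_bottom_cm": ks.layer[1] * 100.0,
                        "n_depths": ks.n_depths_per_wavelength,
                    }
                )
            )
            depths, ratios = rfr_profile(fld)
            rfr_rows.append(
                pd.DataFrame(
                    {
                        "site": site,
                        "density_class": dclass,
                        "depth_cm": depths * 100.0,
                        "rfr": ratios,
                    }
                )
            )
        tables["kd"] = pd.concat(kd_rows, ignore_index=True)
        tables["rfr_profile"] = pd.concat(rfr_rows, ignore_index=True)
        rfr_df = tables["rfr_profile"]

    if "par" in inputs:
        profiles = cio.read_par(inputs["par"])
        rows = []
        for (site, dclass), prof in profiles.items():
            z = prof.depths_m
            rows.append(
                {
                    "site": site,
                    "density_class": dclass,
                    "surface_par": prof.par[0],
                    "absorbed_top10cm_percent": fraction_absorbed(prof, z[0], 0.10)
                    if z[-1] >= 0.10
                    else np.nan,
                    "half_light_depth_m": light_level_depth(prof, 0.5),
                    "euphotic_1pct_depth_m": light_level_depth(prof, 0.01),
                }
            )
        tables["light_summary"] = pd.DataFrame(rows)
        par_df = pd.read_csv(inputs["par"])

    # --- fluorometry ----------------------------------------------------
    if "fluoro" in inputs:
        traces = cio.read_fluoro(inputs["fluoro"])
        step_tabs, fit_rows = [], []
        for tr in traces:
            try:
                tab, fit = process_trace(tr, af=config.af)
            except ValueError as exc:
                log.exclude(f"trace {tr.leaf_id}", "FIT_INPUT", str(exc))
                continue
            n_flagged = int(tab["flagged"].sum())
            if n_flagged:
                log.warn(f"trace {tr.leaf_id}: {n_flagged} out-of-range yield(s)")
            for _, row in tab[~tab["in_fit"]].iterrows():
                log.exclude(
                    f"trace {tr.leaf_id} step {int(row['step'])}",
                    "MISSING_STEP",
                    "Fs or Fm' missing",
                )
            if not fit.converged:
                log.warn(f"trace {tr.leaf_id}: light-curve fit did not converge")
            step_tabs.append(tab)
            fit_rows.append(
                {
                    "leaf_id": tr.leaf_id,
                    "depth_cm": tr.depth_cm,
                    "etr_max": fit.etr_max,
                    "alpha": fit.alpha,
                    "i_k": fit.i_k,
                    "sse": fit.residual_sse,
                    "converged": fit.converged,
                    "n_points": fit.n_points,
                }
            )
        tables["fluoro_params"] = pd.concat(step_tabs, ignore_index=True)
        tables["light_curves"] = pd.DataFrame(fit_rows)

    # --- pigments -------------------------------------------------------
    if "pigments" in inputs:
        rows = []
        for s in cio.read_pigments(inputs["pigments"]):
            res = pigment_concentrations(s, equation_set=config.equation_set)
            if res.flagged:
                log.warn(f"pigment sample {s.leaf_id}: negative concentration kept")
            rows.append(
                {
                    "leaf_id": s.leaf_id,
                    "depth_cm": s.depth_cm,
                    "chl_a_ug_ml": res.chl_a_ug_ml,
                    "chl_b_ug_ml": res.chl_b_ug_ml,
                    "car_ug_ml": res.car_ug_ml,
                    "chl_a_ug_cm2": res.chl_a_ug_cm2,
                    "chl_b_ug_cm2": res.chl_b_ug_cm2,
                    "car_ug_cm2": res.car_ug_cm2,
                    "total_chl_ug_cm2": res.total_chl_ug_cm2,
                    "chl_ab_ratio": res.chl_ab_ratio,
                    "chl_car_ratio": res.chl_car_ratio,
                    "flagged": res.flagged,
                }
            )
        tables["pigment_results"] = pd.DataFrame(rows)

    # --- canopy layers --------------------------------------------------
    if "biomass" in inputs:
        rows = []
        for site, dclass, layer in cio.read_biomass(inputs["biomass"]):
            dens = volumetric_density(layer)
            rows.append(
                {
                    "site": site,
                    "density_class": dclass,
                    "layer_top_cm": layer.layer[0],
                    "layer_bottom_cm": layer.layer[1],
                    "total_g_m3": dens["total_g_m3"],
                    "leaf_g_m3": dens["leaf_g_m3"],
                    "lai_cm2_m3": dens["lai_cm2_m3"],
                    "assimilatory_percent": assimilatory_ratio(layer),
                }
            )
        tables["layers"] = pd.DataFrame(rows)

    # --- morphometrics --------------------------------------------------
    morpho_df = None
    if "morpho" in inputs:
        morpho_df = cio.read_morpho(inputs["morpho"])
        tables["morpho_summary"] = morphometrics_summary(morpho_df)

    # --- synthesis ------------------------------------------------------
    if "fluoro" in inputs:
        leaf_mat, depth_means = build_trait_matrix(
            tables["light_curves"],
            tables.get("fluoro_params"),
            tables.get("pigment_results"),
            morpho_df,
            rfr_df,
            par_df,
        )
        tables["trait_matrix"] = leaf_mat
        tables["trait_matrix_depth_means"] = depth_means
        tables["trait_cv"] = trait_cv(leaf_mat)

        env_present = [c for c in ("depth_cm", "par_umol_m2_s", "rfr")
                       if c in depth_means.columns]
        drop = {"sse", "n_points", "i_k", "converged"} | set(env_present)
        trait_cols = [
            c for c in depth_means.columns
            if c not in drop and pd.api.types.is_numeric_dtype(depth_means[c])
        ]
        tables["correlations"] = correlate_traits(
            depth_means,
            traits=trait_cols + ["i_k"],
            env_cols=tuple(env_present),
        )
        try:
            scores, loadings, pct = pca_traits(depth_means, traits=trait_cols)
            scores = scores.copy()
            scores.insert(0, "depth_cm", depth_means.loc[scores.index, "depth_cm"].values)
            tables["pca_scores"] = scores
            loadings = loadings.reset_index().rename(columns={"index": "trait"})
            tables["pca_loadings"] = loadings
            tables["pca_variance"] = pd.DataFrame(
                {"axis": [f"pc{k+1}" for k in range(len(pct))],
                 "percent_variance": pct}
            )
        except ValueError as exc:
            log.warn(f"PCA skipped: {exc}")

        if morpho_df is not None:
            la = morpho_df.groupby("depth_cm", as_index=False)["area_cm2"].mean()
            em = tables["light_curves"].groupby("depth_cm", as_index=False)[
                "etr_max"
            ].mean()
            joined = em.merge(la, on="depth_cm").sort_values("depth_cm")
            assim = potential_assimilation(
                joined["depth_cm"].to_numpy(),
                joined["etr_max"].to_numpy(),
                joined["area_cm2"].to_numpy(),
            )
            assim["apical"] = assim["depth_cm"] <= config.top_depth_cm
            tables["assimilation"] = assim
            share = apical_share(assim, config.top_depth_cm)
            log.info(
                f"apical (top {config.top_depth_cm:g} cm) assimilation share: "
                f"{share:.2f}%"
            )

    if config.strict and log.warnings:
        raise PipelineError(
            "strict mode: warnings present:\n" + "\n".join(log.warnings)
        )

    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    log.info(f"wrote {len(tables)} table(s) to {out_dir}")
    (out_dir / "run.log").write_text("\n".join(log.lines) + "\n")
    return tables
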