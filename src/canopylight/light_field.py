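"""Depth-resolved underwater light fields.

Turns spectroradiometric and PAR profiles measured at a ladder of depths
into the quantities littoral optics works with: the spectral diffuse
attenuation coefficient Kd(λ) (the log-linear decay rate of downwelling
irradiance Ed with depth), the red:far-red ratio r/fr = Ed(650)/Ed(750)
that plants read as a shade cue, and simple absorption summaries of a
water layer (percent of PAR absorbed, depth where PAR falls to a given
fraction of the surface value).

Irradiance units are treated as relative throughout: every quantity here
is a ratio or a log-slope, so absolute radiometric calibration is never
required — only that all scans of one field share units and wavelength
grid.  Missing or non-positive readings propagate as NaN, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralScan",
    "SpectralField",
    "ParProfile",
    "KdSpectrum",
    "average_replicates",
    "kd_two_point",
    "kd_regression",
    "red_farred",
    "rfr_profile",
    "fraction_absorbed",
    "light_level_depth",
]

#: The nine measurement depths (m) used for field profiles.
CANONICAL_DEPTHS_M = (0.0, 0.10, 0.30, 0.50, 0.70, 0.90, 1.10, 1.30, 1.50)

DENSITY_CLASSES = ("open_water", "low", "moderate", "high")


@dataclass(frozen=True)
class SpectralScan:
    """One downwelling irradiance spectrum Ed(λ) at a single depth."""

    depth_m: float
    wavelengths_nm: np.ndarray
    ed: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ed = np.asarray(self.ed, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "ed", ed)
        if self.depth_m < 0:
            raise ValueError(f"depth_m must be non-negative, got {self.depth_m}")
        if wl.ndim != 1 or ed.shape != wl.shape:
            raise ValueError("wavelengths_nm and ed must be 1-D arrays of equal length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(ed[np.isfinite(ed)] < 0):
            raise ValueError("irradiance values must be >= 0")


@dataclass
class SpectralField:
    """Spectral scans at strictly increasing depths for one site/patch."""

    scans: list[SpectralScan]
    site_label: str = ""
    density_class: str = "open_water"

    def __post_init__(self) -> None:
        if self.density_class not in DENSITY_CLASSES:
            raise ValueError(
                f"density_class must be one of {DENSITY_CLASSES}, got {self.density_class!r}"
            )
        depths = [s.depth_m for s in self.scans]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("scans must be ordered by strictly increasing depth")
        grids = [s.wavelengths_nm for s in self.scans]
        for g in grids[1:]:
            if g.shape != grids[0].shape or not np.array_equal(g, grids[0]):
                raise ValueError("all scans of a field must share one wavelength grid")

    @property
    def depths_m(self) -> np.ndarray:
        return np.array([s.depth_m for s in self.scans])

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.scans[0].wavelengths_nm

    @property
    def ed_matrix(self) -> np.ndarray:
        """Irradiance as (n_depths, n_wavelengths)."""
        return np.vstack([s.ed for s in self.scans])


@dataclass
class ParProfile:
    """Photosynthetic photon flux density (µmol m⁻² s⁻¹) vs depth."""

    depths_m: np.ndarray
    par: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.depths_m, dtype=float)
        p = np.asarray(self.par, dtype=float)
        self.depths_m, self.par = z, p
        if z.ndim != 1 or p.shape != z.shape:
            raise ValueError("depths_m and par must be 1-D arrays of equal length")
        if z.size >= 2 and not np.all(np.diff(z) > 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(p[np.isfinite(p)] < 0):
            raise ValueError("PAR values must be >= 0")


@dataclass
class KdSpectrum:
    """Spectral diffuse attenuation coefficient over one depth layer."""

    wavelengths_nm: np.ndarray
    kd: np.ndarray
    layer: tuple[float, float]
    n_depths_used: int = 0
    n_depths_per_wavelength: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.layer[0] >= self.layer[1]:
            raise ValueError(f"layer requires z_top < z_bottom, got {self.layer}")


def average_replicates(scans: list[SpectralScan]) -> SpectralScan:
    """Element-wise mean of replicate scans taken at one depth.

    Field protocols record several independent spectra per depth; the
    analysis works on their arithmetic mean.
    """
    if not scans:
        raise ValueError("no scans to average")
    ref = scans[0]
    for s in scans[1:]:
        if s.depth_m != ref.depth_m:
            raise ValueError(
                f"replicates must share a depth: {s.depth_m} m vs {ref.depth_m} m"
            )
        if s.wavelengths_nm.shape != ref.wavelengths_nm.shape or not np.array_equal(
            s.wavelengths_nm, ref.wavelengths_nm
        ):
            raise ValueError("replicates must share one wavelength grid")
    mean_ed = np.mean([s.ed for s in scans], axis=0)
    return SpectralScan(ref.depth_m, ref.wavelengths_nm.copy(), mean_ed)


def kd_two_point(
    ed_upper: np.ndarray | float, ed_lower: np.ndarray | float, dz_m: float
) -> np.ndarray | float:
    """Two-depth attenuation coefficient Kd = ln(Ed_upper/Ed_lower)/Δz.

    Negative values (irradiance increasing with depth, i.e. measurement
    noise) are preserved, not clipped.  Non-positive irradiance at a
    wavelength yields NaN there rather than raising.
    """
    if dz_m <= 0:
        raise ValueError(f"dz_m must be > 0, got {dz_m}")
    up = np.asarray(ed_upper, dtype=float)
    lo = np.asarray(ed_lower, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        kd = np.where((up > 0) & (lo > 0), np.log(up / lo) / dz_m, np.nan)
    if np.isscalar(ed_upper) and np.isscalar(ed_lower):
        return float(kd)
    return kd


def kd_regression(
    field: SpectralField, layer: tuple[float, float] | None = None
) -> KdSpectrum:
    """Kd(λ) as minus the OLS slope of ln Ed(λ) against depth.

    Depths inside ``layer`` (inclusive; default the field's full span)
    enter the fit; at each wavelength only depths with Ed > 0 are usable
    and at least two are required, otherwise Kd is NaN there.  With
    exactly two usable depths the slope reduces to :func:`kd_two_point`.
    """
    depths = field.depths_m
    if layer is None:
        layer = (float(depths[0]), float(depths[-1]))
    z_top, z_bottom = layer
    sel = (depths >= z_top - 1e-12) & (depths <= z_bottom + 1e-12)
    if sel.sum() < 2:
        raise ValueError(
            f"need >= 2 depths inside layer {layer}, have {int(sel.sum())}"
        )
    z = depths[sel]
    ed = field.ed_matrix[sel]  # (n_z, n_wl)
    with np.errstate(divide="ignore"):
        ln_ed = np.where(ed > 0, np.log(np.where(ed > 0, ed, 1.0)), np.nan)

    n_wl = ed.shape[1]
    kd = np.full(n_wl, np.nan)
    n_used = np.zeros(n_wl, dtype=int)
    for j in range(n_wl):
        y = ln_ed[:, j]
        ok = np.isfinite(y)
        m = int(ok.sum())
        n_used[j] = m
        if m < 2:
            continue
        zz, yy = z[ok], y[ok]
        zc = zz - zz.mean()
        slope = float(zc @ (yy - yy.mean()) / (zc @ zc))
        kd[j] = -slope
    return KdSpectrum(
        wavelengths_nm=field.wavelengths_nm.copy(),
        kd=kd,
        layer=(z_top, z_bottom),
        n_depths_used=int(sel.sum()),
        n_depths_per_wavelength=n_used,
    )


def _interp_ed(scan: SpectralScan, wavelength_nm: float) -> float:
    wl = scan.wavelengths_nm
    if wavelength_nm < wl[0] or wavelength_nm > wl[-1]:
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside grid [{wl[0]}, {wl[-1]}]"
        )
    return float(np.interp(wavelength_nm, wl, scan.ed))


def red_farred(scan: SpectralScan) -> float:
    """Red:far-red ratio Ed(650)/Ed(750).

    Ed at exactly 650 and 750 nm is obtained by linear interpolation
    between the bracketing grid points (spectrometer grids rarely hit
    integer wavelengths).  Returns NaN when Ed(750) is zero.
    """
    e650 = _interp_ed(scan, 650.0)
    e750 = _interp_ed(scan, 750.0)
    if e750 == 0:
        return float("nan")
    return e650 / e750


def rfr_profile(field: SpectralField) -> tuple[np.ndarray, np.ndarray]:
    """red_farred mapped over a field's depths → (depths_m, r/fr)."""
    return field.depths_m, np.array([red_farred(s) for s in field.scans])


def _log_interp_par(profile: ParProfile, z: float) -> float:
    # exponential attenuation is the physical model, so interpolate ln(PAR)
    depths, par = profile.depths_m, profile.par
    if z < depths[0] or z > depths[-1]:
        raise ValueError(f"depth {z} m outside profile [{depths[0]}, {depths[-1]}] m")
    if np.any(par <= 0):
        raise ValueError("log-space interpolation needs strictly positive PAR")
    return float(np.exp(np.interp(z, depths, np.log(par))))


def fraction_absorbed(profile: ParProfile, z_top: float, z_bottom: float) -> float:
    """Percent of PAR entering at ``z_top`` absorbed by ``z_bottom``.

    100·(1 − PAR(z_bottom)/PAR(z_top)); depths not on the measurement
    ladder are interpolated in log space.  NaN when PAR(z_top) is zero.
    """
    if z_top >= z_bottom:
        raise ValueError("requires z_top < z_bottom")
    p_top = _log_interp_par(profile, z_top)
    p_bot = _log_interp_par(profile, z_bottom)
    if p_top == 0:
        return float("nan")
    return 100.0 * (1.0 - p_bot / p_top)


def light_level_depth(profile: ParProfile, fraction: float) -> float:
    """Shallowest depth where PAR falls to ``fraction`` of the surface value.

    Linear interpolation in ln(PAR); e.g. ``fraction=0.5`` gives the
    half-light depth, ``fraction=0.01`` the 1% euphotic limit.  Returns
    NaN when the level is not reached within the profile.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    depths, par = profile.depths_m, profile.par
    if par[0] <= 0:
        raise ValueError("surface PAR must be > 0")
    if np.any(par <= 0):
        raise ValueError("profile must be strictly positive for log interpolation")
    y = np.log(par / par[0])
    target = np.log(fraction)
    if y[0] <= target:
        return float(depths[0])
    for i in range(1, len(depths)):
        if y[i] <= target:
            t = (target - y[i - 1]) / (y[i] - y[i - 1])
            return float(depths[i - 1] + t * (depths[i] - depths[i - 1]))
    return float("nan")
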