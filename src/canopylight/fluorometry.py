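"""PAM chlorophyll-fluorescence parameters and rapid light curves.

Standard quenching analysis: a dark-adapted leaf yields F0 (minimum) and
Fm (maximum) fluorescence; each subsequent actinic light step yields the
apparent fluorescence Fs and the light-adapted maximum Fm′ after a
saturating pulse.  From these come

    Fv/Fm = (Fm − F0)/Fm            maximum PSII quantum efficiency
    qP    = (Fm′ − Fs)/(Fm′ − F0′)  photochemical quenching
    qN    = 1 − (Fm′ − F0′)/(Fm − F0)   non-photochemical quenching
    ETR   = (Fm′ − Fs)/Fm′ · I · AF · 0.5

with AF the empirical leaf absorption factor (default 0.84) and the 0.5
splitting absorbed photons between the two photosystems.  The ETR vs
irradiance response is fitted with the Webb exponential saturation model

    ETR(I) = ETRmax · (1 − exp(−α·I/ETRmax)),

whose initial slope is α and whose saturation onset is Ik = ETRmax/α
(a derived quantity, never fitted independently).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "LightStep",
    "InductionTrace",
    "LightCurveFit",
    "fv_fm",
    "f0_prime_estimate",
    "qp",
    "qn",
    "etr",
    "webb_model",
    "fit_light_curve",
    "process_trace",
    "DEFAULT_AF",
]

DEFAULT_AF = 0.84


@dataclass(frozen=True)
class LightStep:
    """One actinic illumination step of a rapid light curve."""

    i: float  # actinic irradiance, µmol m⁻² s⁻¹
    fs: float  # apparent fluorescence (a.u.)
    fm_prime: float  # light-adapted maximum fluorescence (a.u.)
    f0_prime: float | None = None  # measured light-adapted minimum, if any

    def __post_init__(self) -> None:
        if self.i < 0:
            raise ValueError(f"irradiance must be >= 0, got {self.i}")
        if not math.isnan(self.fs) and not math.isnan(self.fm_prime):
            if self.fs < 0:
                raise ValueError("fs must be >= 0")


@dataclass
class InductionTrace:
    """Dark-adapted yields plus the ordered light-step sequence for one leaf."""

    f0: float
    fm: float
    steps: list[LightStep]
    leaf_id: str = ""
    depth_cm: float = float("nan")

    def __post_init__(self) -> None:
        if not 0 < self.f0 < self.fm:
            raise ValueError(
                f"requires 0 < F0 < Fm, got F0={self.f0}, Fm={self.fm}"
            )
        irr = [s.i for s in self.steps]
        if any(b <= a for a, b in zip(irr, irr[1:])):
            raise ValueError("step irradiances must be strictly increasing")


@dataclass
class LightCurveFit:
    """Webb-model parameters for one rapid light curve."""

    etr_max: float
    alpha: float
    residual_sse: float
    converged: bool
    n_points: int

    @property
    def i_k(self) -> float:
        """Saturation onset Ik = ETRmax/α — always the derived ratio."""
        return self.etr_max / self.alpha


def fv_fm(f0: float, fm: float) -> float:
    """Maximum quantum efficiency of PSII, (Fm − F0)/Fm."""
    if not 0 < f0 < fm:
        raise ValueError(f"requires 0 < F0 < Fm, got F0={f0}, Fm={fm}")
    return (fm - f0) / fm


def f0_prime_estimate(f0: float, fm: float, fm_prime: float) -> float:
    """Estimate the light-adapted minimum fluorescence F0′ when not measured.

    Oxborough–Baker form: F0′ = F0 / (Fv/Fm + F0/Fm′).  Reduces to F0
    when Fm′ = Fm (no quenching).  Fm′ slightly above Fm — measurement
    noise near the dark state — is accepted; the formula stays defined.
    """
    if not 0 < f0 < fm:
        raise ValueError(f"requires 0 < F0 < Fm, got F0={f0}, Fm={fm}")
    if fm_prime <= 0:
        raise ValueError(f"requires Fm' > 0, got Fm'={fm_prime}")
    return f0 / (fv_fm(f0, fm) + f0 / fm_prime)


def qp(fs: float, fm_prime: float, f0_prime: float) -> float:
    """Photochemical quenching (Fm′ − Fs)/(Fm′ − F0′).

    In [0, 1] when F0′ ≤ Fs ≤ Fm′; out-of-range values are returned
    as-is (callers flag them), NaN when Fm′ = F0′.
    """
    if fm_prime == f0_prime:
        return float("nan")
    if f0_prime > fm_prime:
        raise ValueError(f"requires F0' < Fm', got F0'={f0_prime}, Fm'={fm_prime}")
    return (fm_prime - fs) / (fm_prime - f0_prime)


def qn(fm_prime: float, f0_prime: float, fm: float, f0: float) -> float:
    """Non-photochemical quenching 1 − (Fm′ − F0′)/(Fm − F0)."""
    if fm <= f0:
        raise ValueError(f"requires Fm > F0, got Fm={fm}, F0={f0}")
    return 1.0 - (fm_prime - f0_prime) / (fm - f0)


def etr(fs: float, fm_prime: float, i: float, af: float = DEFAULT_AF) -> float:
    """Electron transport rate (Fm′ − Fs)/Fm′ · I · AF · 0.5 (µmol e⁻ m⁻² s⁻¹).

    Fs > Fm′ produces a negative rate, which is reported, not clipped.
    """
    if fm_prime <= 0:
        raise ValueError(f"requires Fm' > 0, got {fm_prime}")
    if i < 0:
        raise ValueError(f"requires I >= 0, got {i}")
    return (fm_prime - fs) / fm_prime * i * af * 0.5


def webb_model(i: np.ndarray, etr_max: float, alpha: float) -> np.ndarray:
    """Exponential saturation light response ETRmax·(1 − exp(−α·I/ETRmax))."""
    return etr_max * (1.0 - np.exp(-alpha * np.asarray(i, float) / etr_max))


def fit_light_curve(
    points: list[tuple[float, float]] | np.ndarray,
    max_nfev: int = 10_000,
    xtol: float = 1e-8,
    x0: tuple[float, float] | None = None,
) -> LightCurveFit:
    """Least-squares fit of the Webb model to (irradiance, ETR) points.

    Initialisation: α₀ from the least-squares line through the origin
    over the three lowest irradiances; ETRmax₀ = max observed ETR
    (``x0 = (etr_max0, alpha0)`` overrides both).  Both parameters are
    bounded below by zero.  Points with NaN in either coordinate are
    dropped; at least four distinct irradiances with one in the
    light-limited region (I < max(I)/4) are required.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (i, etr)")
    arr = arr[np.all(np.isfinite(arr), axis=1)]
    if arr.shape[0] < 4 or np.unique(arr[:, 0]).size < 4:
        raise ValueError("need >= 4 points with distinct irradiances")
    i_obs, e_obs = arr[:, 0], arr[:, 1]
    if not np.any(i_obs < i_obs.max() / 4):
        raise ValueError("no point in the light-limited region (I < max(I)/4)")

    if x0 is not None:
        etrmax0, alpha0 = float(x0[0]), float(x0[1])
    else:
        order = np.argsort(i_obs)
        low = order[:3]
        denom = float(i_obs[low] @ i_obs[low])
        alpha0 = float(i_obs[low] @ e_obs[low]) / denom if denom > 0 else 0.1
        alpha0 = max(alpha0, 1e-6)
        etrmax0 = max(float(e_obs.max()), 1e-6)

    def resid(theta: np.ndarray) -> np.ndarray:
        return webb_model(i_obs, theta[0], theta[1]) - e_obs

    sol = least_squares(
        resid,
        x0=[etrmax0, alpha0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=xtol,
        ftol=xtol,
        gtol=None,
        max_nfev=max_nfev,
    )
    sse = float(sol.fun @ sol.fun)
    return LightCurveFit(
        etr_max=float(sol.x[0]),
        alpha=float(sol.x[1]),
        residual_sse=sse,
        converged=bool(sol.success),
        n_points=int(arr.shape[0]),
    )


def process_trace(
    trace: InductionTrace, af: float = DEFAULT_AF
) -> tuple[pd.DataFrame, LightCurveFit]:
    """Quenching analysis of one induction trace plus the light-curve fit.

    Returns one row per light step with qP, qN and ETR (F0′ taken from
    the measurement when present, otherwise the Oxborough–Baker
    estimate, recorded in ``f0_prime_source``), and the Webb fit over
    the usable steps.  Steps with missing Fs or Fm′ are excluded from
    the fit but kept in the table.
    """
    if not trace.steps:
        raise ValueError("trace has no light steps")
    fvfm = fv_fm(trace.f0, trace.fm)
    rows = []
    for k, s in enumerate(trace.steps):
        usable = (
            np.isfinite(s.fs) and np.isfinite(s.fm_prime) and s.fm_prime > 0
        )
        if usable:
            if s.f0_prime is not None and np.isfinite(s.f0_prime):
                f0p, f0p_src = float(s.f0_prime), "measured"
            else:
                f0p, f0p_src = f0_prime_estimate(trace.f0, trace.fm, s.fm_prime), "estimated"
            qp_val = qp(s.fs, s.fm_prime, f0p)
            qn_val = qn(s.fm_prime, f0p, trace.fm, trace.f0)
            etr_val = etr(s.fs, s.fm_prime, s.i, af=af)
            yield_val = (s.fm_prime - s.fs) / s.fm_prime
            flagged = not (0.0 <= qp_val <= 1.0) or not (0.0 <= yield_val <= 1.0)
        else:
            f0p, f0p_src = float("nan"), "missing"
            qp_val = qn_val = etr_val = float("nan")
            flagged = False
        rows.append(
            {
                "leaf_id": trace.leaf_id,
                "depth_cm": trace.depth_cm,
                "step": k + 1,
                "i_umol_m2_s": s.i,
                "fv_fm": fvfm,
                "f0_prime": f0p,
                "f0_prime_source": f0p_src,
                "qp": qp_val,
                "qn": qn_val,
                "etr": etr_val,
                "flagged": flagged,
                "in_fit": usable,
            }
        )
    table = pd.DataFrame(rows)
    fit_pts = table.loc[table["in_fit"], ["i_umol_m2_s", "etr"]].to_numpy()
    fit = fit_light_curve(fit_pts)
    return table, fit
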