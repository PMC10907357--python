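"""Within-plant synthesis statistics.

Where the other modules measure, this one aggregates: the vertical
distribution of potential photosynthetic assimilation (ETRmax × leaf
area, as percent of the plant total), depth profiles of trait
variability (coefficient of variation), Pearson correlations between
leaf traits and the light environment (depth, PAR, r/fr), and a
standardized PCA of the trait matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "CANONICAL_LEAF_LEVELS_CM",
    "potential_assimilation",
    "apical_share",
    "trait_cv",
    "correlate_traits",
    "significance_stars",
    "pca_traits",
]

#: Midpoint depths (cm) of the leaf sampling intervals 0–1, 1–10, 10–30, … cm.
CANONICAL_LEAF_LEVELS_CM = (1, 5, 20, 40, 60, 80, 100, 120, 140)

#: Environment descriptors, never part of the PCA trait set.
ENVIRONMENT_COLUMNS = ("depth_cm", "par_umol_m2_s", "rfr")


def potential_assimilation(
    levels_cm, etr_max, leaf_area_cm2
) -> pd.DataFrame:
    """Per-level potential assimilation ETRmax·LA and its percent of plant total.

    Percent contributions sum to 100 exactly (up to float rounding).
    Raises when every product is zero — no assimilating tissue at all.
    """
    levels = np.asarray(levels_cm, dtype=float)
    em = np.asarray(etr_max, dtype=float)
    la = np.asarray(leaf_area_cm2, dtype=float)
    if not (levels.shape == em.shape == la.shape):
        raise ValueError("levels, etr_max and leaf_area must have equal length")
    if np.any(np.diff(levels) <= 0):
        raise ValueError("levels must be strictly increasing")
    if np.any(la < 0):
        raise ValueError("leaf area must be >= 0")
    product = em * la
    total = product.sum()
    if total <= 0:
        raise ValueError("all assimilation products are zero")
    return pd.DataFrame(
        {
            "depth_cm": levels,
            "etr_max": em,
            "leaf_area_cm2": la,
            "product": product,
            "percent": 100.0 * product / total,
        }
    )


def apical_share(assim: pd.DataFrame, top_depth_cm: float = 40.0) -> float:
    """Percent of whole-plant potential assimilation at levels ≤ ``top_depth_cm``."""
    return float(assim.loc[assim["depth_cm"] <= top_depth_cm, "percent"].sum())


def trait_cv(
    matrix: pd.DataFrame,
    traits: list[str] | None = None,
    grouping: str = "depth_cm",
) -> pd.DataFrame:
    """Coefficient of variation (sd/mean, as a fraction) per group per trait.

    Sample (ddof=1) standard deviation; NaN when a group has fewer than
    two finite replicates or a zero mean.
    """
    if grouping not in matrix.columns:
        raise ValueError(f"grouping column {grouping!r} not in matrix")
    if traits is None:
        traits = [
            c
            for c in matrix.columns
            if c != grouping
            and c not in ENVIRONMENT_COLUMNS
            and pd.api.types.is_numeric_dtype(matrix[c])
        ]
    rows = []
    for key, grp in matrix.groupby(grouping):
        for t in traits:
            vals = grp[t].dropna().to_numpy(dtype=float)
            if vals.size < 2 or vals.mean() == 0:
                cv = float("nan")
            else:
                cv = float(vals.std(ddof=1) / vals.mean())
            rows.append({grouping: key, "trait": t, "n": vals.size, "cv": cv})
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Conventional per-test significance marks: * <0.05, ** <0.01, *** <0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlate_traits(
    matrix: pd.DataFrame,
    traits: list[str] | None = None,
    env_cols: tuple[str, ...] = ENVIRONMENT_COLUMNS,
) -> pd.DataFrame:
    """Pearson r (with unadjusted two-sided p) of each trait against each
    environment descriptor.

    Pairs with fewer than three complete observations or zero variance
    in either column give NaN.
    """
    if traits is None:
        traits = [
            c
            for c in matrix.columns
            if c not in env_cols and pd.api.types.is_numeric_dtype(matrix[c])
        ]
    rows = []
    for t in traits:
        for e in env_cols:
            if e not in matrix.columns:
                continue
            sub = matrix[[t, e]].dropna()
            x, y = sub[t].to_numpy(float), sub[e].to_numpy(float)
            if len(sub) < 3 or np.std(x) == 0 or np.std(y) == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(x, y)
            rows.append(
                {
                    "trait": t,
                    "environment": e,
                    "n": len(sub),
                    "r": r,
                    "p": p,
                    "significance": significance_stars(p),
                }
            )
    return pd.DataFrame(rows)


def pca_traits(
    matrix: pd.DataFrame, traits: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Correlation-matrix PCA of the trait table.

    Columns are z-scored (population sd) before decomposition, which is
    the right scaling for traits in mixed units; constant columns are
    dropped with a warning.  Loadings are orthonormal with a
    deterministic sign convention (the largest-magnitude loading of each
    axis is positive); variance percentages sum to 100 over all axes.

    Returns ``(scores, loadings, percent_variance)``.
    """
    if traits is None:
        traits = [
            c
            for c in matrix.columns
            if c not in ENVIRONMENT_COLUMNS and pd.api.types.is_numeric_dtype(matrix[c])
        ]
    data = matrix[traits].dropna()
    if data.shape[0] < 3 or data.shape[1] < 2:
        raise ValueError("PCA needs >= 3 complete rows and >= 2 traits")
    kept = []
    for c in traits:
        if data[c].std(ddof=0) == 0:
            warnings.warn(f"dropping constant trait column {c!r} from PCA", stacklevel=2)
        else:
            kept.append(c)
    if len(kept) < 2:
        raise ValueError("fewer than 2 non-constant traits")
    x = data[kept].to_numpy(dtype=float)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)

    pca = PCA(n_components=min(z.shape))
    scores = pca.fit_transform(z)
    loadings = pca.components_  # (n_axes, n_traits), orthonormal rows
    for a in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[a]))
        if loadings[a, j] < 0:
            loadings[a] *= -1.0
            scores[:, a] *= -1.0
    pct = 100.0 * pca.explained_variance_ratio_

    axes = [f"pc{k + 1}" for k in range(loadings.shape[0])]
    scores_df = pd.DataFrame(scores, index=data.index, columns=axes)
    loadings_df = pd.DataFrame(loadings.T, index=kept, columns=axes)
    return scores_df, loadings_df, pct
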