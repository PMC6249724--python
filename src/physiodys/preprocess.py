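"""Pre-treatment of the physiological panel.

Covers variable transformations, the corticosterone outlier policy, the
two-variable immune (agglutination + lysis) and oxidative (OXY + dROMs)
composite PCs, within-female stage deltas, regression-based year/stage
standardization, wing loading, and proportional partitioning of unknown-sex
nest visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CHICK_REARING, INCUBATION

__all__ = [
    "DEFAULT_TRANSFORM_MAP",
    "normalize_variables",
    "exclude_cort_outliers",
    "CompositePCs",
    "immune_composite",
    "oxidative_composite",
    "DeltaPanel",
    "compute_delta",
    "StandardizedPanel",
    "standardize_by_cell",
    "wing_loading",
    "partition_unknown_visits",
]

# Per-variable normalizing transforms.  The exact assignment is a package
# default (configurable): natural log for right-skewed plasma assays, square
# root for reticulocyte percentages, identity otherwise.
DEFAULT_TRANSFORM_MAP = {
    "corticosterone": "log",
    "creatine_kinase": "log",
    "triglycerides": "log",
    "droms": "log",
    "haptoglobin": "log",
    "reticulocytes": "sqrt",
}


def normalize_variables(
    data: pd.DataFrame, transform_map: dict | None = None
) -> tuple[pd.DataFrame, dict]:
    """Apply log/sqrt transforms in place of the raw columns.

    Returns the transformed frame and the mapping actually applied (for the
    processing log).  Raises on non-positive values under ``log`` (or negative
    under ``sqrt``) listing the offending row indices.
    """
    tmap = DEFAULT_TRANSFORM_MAP if transform_map is None else transform_map
    out = data.copy()
    applied = {}
    for col, how in tmap.items():
        if col not in out.columns:
            continue
        if how not in ("none", "log", "sqrt"):
            raise ValueError(f"{col}: unknown transform {how!r}")
        if how == "none":
            applied[col] = "none"
            continue
        x = out[col]
        if how == "log":
            bad = out.index[(x <= 0) & x.notna()]
            if len(bad):
                raise ValueError(
                    f"log transform of {col!r}: non-positive values at rows "
                    f"{list(bad[:10])}"
                )
            out[col] = np.log(x)
        else:
            bad = out.index[(x < 0) & x.notna()]
            if len(bad):
                raise ValueError(
                    f"sqrt transform of {col!r}: negative values at rows "
                    f"{list(bad[:10])}"
                )
            out[col] = np.sqrt(x)
        applied[col] = how
    return out, applied


def exclude_cort_outliers(
    data: pd.DataFrame,
    threshold: float = 80.0,
    column: str = "corticosterone",
    id_column: str = "female_id",
) -> tuple[pd.DataFrame, list]:
    """Drop females with baseline corticosterone strictly above ``threshold``.

    The cut (default 80 ng/ml, i.e. stress-induced territory for this species)
    applies to the univariate analysis path only; multivariate analyses keep
    these rows for sample size and handle them through sensitivity flags.
    Returns (filtered data, sorted excluded female ids).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if data.empty:
        return data.copy(), []
    flagged = data.loc[data[column] > threshold, id_column]
    excluded = sorted(pd.unique(flagged))
    keep = ~data[id_column].isin(excluded)
    return data.loc[keep].reset_index(drop=True), excluded


@dataclass
class CompositePCs:
    """Two-variable PCA composite: activation (PC1) and balance (PC2) axes."""

    scores: pd.DataFrame            # columns pc1, pc2; indexed like the input
    loadings: np.ndarray            # 2 x 2, columns are axes
    variance_fraction: np.ndarray   # length 2


def _two_variable_pca(x: pd.Series, y: pd.Series, names=("pc1", "pc2")) -> CompositePCs:
    pair = pd.concat([x, y], axis=1)
    complete = pair.dropna()
    if len(complete) < 3:
        raise ValueError("need at least 3 complete pairs")
    arr = complete.to_numpy(dtype=float)
    mu, sd = arr.mean(axis=0), arr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero variance in a composite input")
    z = (arr - mu) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # orientation: activation axis has both loadings positive when the inputs
    # co-vary positively; otherwise make the dominant loading positive
    for k in range(2):
        v = eigvec[:, k]
        if (v <= 0).all() or v[np.argmax(np.abs(v))] < 0:
            eigvec[:, k] = -v
    z_all = (pair.to_numpy(dtype=float) - mu) / sd
    scores = pd.DataFrame(z_all @ eigvec, index=pair.index, columns=list(names))
    frac = np.clip(eigval, 0.0, None)
    frac = frac / frac.sum()
    return CompositePCs(scores, eigvec, frac)


def immune_composite(agglutination: pd.Series, lysis: pd.Series) -> CompositePCs:
    """Natural-antibody composite: PC1 = joint activation, PC2 = balance."""
    return _two_variable_pca(agglutination, lysis, names=("nab_pc1", "nab_pc2"))


def oxidative_composite(oxy: pd.Series, droms: pd.Series) -> CompositePCs:
    """Oxidative-status composite of antioxidant capacity and ROM levels."""
    return _two_variable_pca(oxy, droms, names=("ox_pc1", "ox_pc2"))


@dataclass
class DeltaPanel:
    """Within-female change from incubation to chick-rearing (first brood)."""

    values: pd.DataFrame            # one row per (female_id, year) with both stages
    variables: list
    omitted: list = field(default_factory=list)   # (female_id, year) single-stage


def compute_delta(
    data: pd.DataFrame,
    variables: list,
    id_column: str = "female_id",
    year_column: str = "year",
) -> DeltaPanel:
    """delta = chick-rearing value - incubation value, first brood only."""
    first = data[data["brood"] == 1]
    inc = first[first["stage"] == INCUBATION].set_index([id_column, year_column])
    cr = first[first["stage"] == CHICK_REARING].set_index([id_column, year_column])
    shared = inc.index.intersection(cr.index)
    omitted = sorted(set(inc.index.symmetric_difference(cr.index)))
    delta = cr.loc[shared, variables] - inc.loc[shared, variables]
    delta.columns = [f"delta_{c}" for c in variables]
    return DeltaPanel(delta.reset_index(), [f"delta_{c}" for c in variables], omitted)


@dataclass
class StandardizedPanel:
    """Z-scores after additive regression adjustment of year/stage means.

    Per variable, an additive linear model ``value ~ year + stage`` supplies
    the cell mean to subtract (the four year-stage cells are too small for
    robust direct means), and the residual SD supplies the scale.
    """

    values: pd.DataFrame
    adjustment_betas: pd.DataFrame   # per-variable coefficients
    scale: pd.Series                 # per-variable residual SD
    cell_labels: pd.DataFrame        # (year, stage) per row
    meta: pd.DataFrame               # id columns carried alongside


def standardize_by_cell(
    data: pd.DataFrame,
    variables: list,
    year_column: str = "year",
    stage_column: str = "stage",
    id_columns: tuple = ("female_id", "year", "stage", "brood"),
) -> StandardizedPanel:
    """Regression-based year/stage standardization of the panel columns."""
    counts = data.groupby([year_column, stage_column]).size()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"cells with fewer than 2 observations: {list(small.index)}"
        )
    years = pd.get_dummies(data[year_column], prefix="year", drop_first=True)
    stages = pd.get_dummies(data[stage_column], prefix="stage", drop_first=True)
    X = pd.concat([pd.Series(1.0, index=data.index, name="intercept"),
                   years.astype(float), stages.astype(float)], axis=1)
    Xm = X.to_numpy()

    z = pd.DataFrame(index=data.index, columns=variables, dtype=float)
    betas = {}
    scales = {}
    for col in variables:
        y = data[col].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() <= Xm.shape[1]:
            raise ValueError(f"{col}: too few non-missing values to adjust")
        coef, *_ = np.linalg.lstsq(Xm[ok], y[ok], rcond=None)
        fitted = Xm @ coef
        resid = y - fitted
        dof = ok.sum() - Xm.shape[1]
        sd = float(np.sqrt(np.nansum(resid[ok] ** 2) / dof))
        # an (effectively) exact additive fit has no residual scale to divide
        # by; keep the zero residuals instead of amplifying float noise
        if sd <= 1e-10 * max(1.0, float(np.nanstd(y))):
            sd = 1.0
            resid = np.where(np.abs(resid) < 1e-8, 0.0, resid)
        z[col] = resid / sd
        betas[col] = coef
        scales[col] = sd

    return StandardizedPanel(
        values=z,
        adjustment_betas=pd.DataFrame(betas, index=X.columns).T,
        scale=pd.Series(scales, name="residual_sd"),
        cell_labels=data[[year_column, stage_column]].copy(),
        meta=data[[c for c in id_columns if c in data.columns]].copy(),
    )


def wing_loading(
    mass: pd.Series, area: pd.Series, year: pd.Series
) -> pd.Series:
    """Mass / wing area (g per cm^2), mean-centered within year.

    Measurers differed between years, so only within-year contrasts are
    meaningful; centering removes the between-year offset.
    """
    area = pd.Series(area, dtype=float)
    if (area <= 0).any():
        raise ValueError("wing area must be strictly positive")
    raw = pd.Series(mass, dtype=float) / area
    return raw - raw.groupby(pd.Series(year).values).transform("mean")


def partition_unknown_visits(
    female_known, male_known, unknown
) -> tuple[np.ndarray, np.ndarray]:
    """Allocate unknown-sex nest visits in proportion to the known counts.

    Totals are conserved exactly: f + m + u == f_total + m_total.
    """
    f = np.asarray(female_known, dtype=float)
    m = np.asarray(male_known, dtype=float)
    u = np.asarray(unknown, dtype=float)
    if np.any(f < 0) or np.any(m < 0) or np.any(u < 0):
        raise ValueError("visit counts must be non-negative")
    known = f + m
    if np.any((known == 0) & (u > 0)):
        raise ValueError("cannot partition unknown visits with no known visits")
    share = np.divide(f, known, out=np.zeros_like(f), where=known > 0)
    f_total = f + u * share
    m_total = m + u * (1.0 - share)
    return f_total, m_total
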