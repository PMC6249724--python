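"""Integrated physiology and performance summaries by PCA.

Four flavours:

* directional -- ordinary PCA of the standardized (centered/reduced) panel;
  axes describe signed co-variation.
* deviational -- PCA of ln(|z| + floor), re-centered and re-scaled; axes
  describe the *magnitude* of departure from the adjusted means regardless of
  direction, the structure the dysregulation-distance idea posits.
* group -- PC1 of three-variable functional groups (aerobic capacity,
  metabolism/energy, oxidative stress/muscle damage).
* reproduction -- PC1 of four current-productivity measures, oriented so
  higher scores mean higher productivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

__all__ = [
    "PCAResult",
    "DEFAULT_GROUPS",
    "REPRODUCTION_VARIABLES",
    "directional_pca",
    "deviational_pca",
    "group_pca",
    "reproduction_pca",
]

#: three-variable functional groups entering group PCAs (configurable)
DEFAULT_GROUPS = {
    "aerobic_capacity": ["hematocrit", "hemoglobin", "reticulocytes"],
    "metabolism_energy": ["triglycerides", "nefa", "uric_acid"],
    "oxidative_stress": ["oxy", "droms", "creatine_kinase"],
}

#: current-season productivity measures for the reproduction composite
REPRODUCTION_VARIABLES = [
    "brood_size_d6", "bsf1", "total_fledged_year", "total_fledgling_mass_year",
]


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # variables x axes
    scores: pd.DataFrame            # observations x axes (complete cases)
    variance_fraction: np.ndarray
    kind: str


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic orientation: dominant loading of each axis positive."""
    comp = components.copy()
    for k in range(comp.shape[0]):
        j = np.argmax(np.abs(comp[k]))
        if comp[k, j] < 0:
            comp[k] = -comp[k]
    return comp


def _pca(frame: pd.DataFrame, n_axes: int, kind: str, scale: bool,
         axis_prefix: str) -> PCAResult:
    complete = frame.dropna()
    if len(complete) < n_axes + 1:
        raise ValueError(
            f"{kind} PCA needs at least {n_axes + 1} complete rows, "
            f"got {len(complete)}"
        )
    arr = complete.to_numpy(dtype=float)
    sd = arr.std(axis=0, ddof=1)
    constant = [c for c, s in zip(frame.columns, sd) if s == 0]
    if constant:
        raise ValueError(f"constant column(s) in {kind} PCA input: {constant}")
    if scale:
        arr = (arr - arr.mean(axis=0)) / sd

    fit = _SKPCA(n_components=min(n_axes, arr.shape[1]), svd_solver="full")
    fit.fit(arr)
    comp = _fix_signs(fit.components_)
    scores = (arr - arr.mean(axis=0)) @ comp.T
    axes = [f"{axis_prefix}{k + 1}" for k in range(comp.shape[0])]
    return PCAResult(
        loadings=pd.DataFrame(comp.T, index=frame.columns, columns=axes),
        scores=pd.DataFrame(scores, index=complete.index, columns=axes),
        variance_fraction=fit.explained_variance_ratio_.copy(),
        kind=kind,
    )


def directional_pca(panel, n_axes: int = 3) -> PCAResult:
    """PCA of the standardized panel; first ``n_axes`` retained for testing."""
    return _pca(panel.values, n_axes, "directional", scale=False,
                axis_prefix="dir_pc")


def deviational_pca(panel, n_axes: int = 3, floor: float = 1e-8) -> PCAResult:
    """PCA of ln(|z| + floor): structure in deviation magnitudes.

    The floor keeps exactly-mean observations (z = 0) finite; transformed
    columns are re-centered and re-scaled before decomposition, so the result
    is invariant to sign flips of any input column.
    """
    transformed = np.log(panel.values.abs() + floor)
    return _pca(transformed, n_axes, "deviational", scale=True,
                axis_prefix="dev_pc")


def group_pca(panel, group: str, members: list | None = None) -> PCAResult:
    """PC1 of one functional group (three members by default)."""
    if members is None:
        if group not in DEFAULT_GROUPS:
            raise ValueError(f"unknown functional group {group!r}")
        members = DEFAULT_GROUPS[group]
    if len(members) != 3:
        warnings.warn(
            f"group {group!r} has {len(members)} members (3 expected); "
            "proceeding with the listed members",
            stacklevel=2,
        )
    missing = [m for m in members if m not in panel.values.columns]
    if missing:
        raise ValueError(f"group {group!r}: variables not in panel: {missing}")
    res = _pca(panel.values[members], 1, "group", scale=False,
               axis_prefix=f"{group}_pc")
    return res


def reproduction_pca(outcomes: pd.DataFrame,
                     variables: list | None = None) -> PCAResult:
    """Composite productivity axis from four breeding-success measures.

    PC1 is oriented so that higher scores mean higher productivity: when all
    pairwise correlations are positive the loadings are all positive, and in
    general the axis is flipped so the loading sum is positive.
    """
    cols = REPRODUCTION_VARIABLES if variables is None else list(variables)
    frame = outcomes[cols]
    if len(frame.dropna()) < 5:
        raise ValueError("reproduction PCA needs at least 5 complete rows")
    res = _pca(frame, 1, "reproduction", scale=True, axis_prefix="repro_pc")
    if res.loadings.iloc[:, 0].sum() < 0:
        res.loadings.iloc[:, 0] *= -1
        res.scores.iloc[:, 0] *= -1
    return res
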