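"""Mahalanobis-distance physiological dysregulation scores.

An observation's dysregulation score is its Mahalanobis distance from a
reference centroid in standardized biomarker space:

    DM = sqrt((x - mu)' S^{-1} (x - mu))

where S is the biomarker covariance (pooled over all complete standardized
rows) and mu encodes the presumed-optimal state.  A score of 0 means the
profile sits exactly at the optimum; scores grow as the profile becomes more
abnormal.  Because several markers plausibly have their optimum away from the
population mean (e.g. lower oxidative activation is better, with no lower
bound), centroids are configurable per biomarker: MEAN (0 on the z scale),
HIGH (+offset_sd) or LOW (-offset_sd), with offset_sd defaulting to 3.

Six shipped versions: v0 (all MEAN), v1-v4 (a-priori direction hypotheses of
increasing reach, illustrative defaults) and v5 (per-biomarker random choice,
one seeded draw).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import StandardizedPanel

__all__ = [
    "MEAN",
    "HIGH",
    "LOW",
    "CentroidSpec",
    "DMConfig",
    "DMScore",
    "default_centroid_specs",
    "random_centroid_spec",
    "build_centroid",
    "mahalanobis",
    "pooled_covariance",
    "score_dm",
    "dm_sensitivity",
]

MEAN, HIGH, LOW = "MEAN", "HIGH", "LOW"

#: default multivariate biomarker set: single markers plus the immune and
#: oxidative composite axes (raw OXY/dROMs and agglutination/lysis enter via
#: their PCs)
DM_VARIABLES = [
    "hematocrit", "hemoglobin", "reticulocytes", "corticosterone",
    "creatine_kinase", "nefa", "triglycerides", "glucose", "uric_acid",
    "haptoglobin", "nab_pc1", "nab_pc2", "ox_pc1", "ox_pc2",
]


@dataclass
class CentroidSpec:
    """Per-biomarker optimum choice defining one DM version."""

    label: str
    choice: dict = field(default_factory=dict)   # biomarker -> MEAN/HIGH/LOW
    offset_sd: float = 3.0

    def validate(self, subset) -> None:
        if self.offset_sd < 0:
            raise ValueError("offset_sd must be non-negative")
        missing = [b for b in subset if self.choice.get(b, MEAN) not in (MEAN, HIGH, LOW)]
        if missing:
            raise ValueError(f"invalid centroid choice for {missing}")


@dataclass
class DMConfig:
    spec: CentroidSpec
    include_reticulocytes: bool = True
    covariance_policy: str = "sample"        # or "shrinkage"
    subset: list = field(default_factory=lambda: list(DM_VARIABLES))

    @property
    def active_subset(self) -> list:
        if self.include_reticulocytes:
            return list(self.subset)
        return [b for b in self.subset if b != "reticulocytes"]

    @property
    def label(self) -> str:
        retics = "with_retics" if self.include_reticulocytes else "no_retics"
        return f"{self.spec.label}_{retics}"


@dataclass
class DMScore:
    """Complete-case DM scores plus the centroid/covariance that produced them."""

    scores: pd.Series                 # indexed like the kept panel rows
    centroid: pd.Series
    covariance: pd.DataFrame
    meta: pd.DataFrame                # ids of kept rows
    dropped: list                     # indices of incomplete-case rows
    config: DMConfig
    condition_number: float
    shrinkage_weight: float = 0.0


def default_centroid_specs() -> list[CentroidSpec]:
    """v0-v4: mean-centroid baseline plus a-priori direction hypotheses.

    v1: low oxidative activation/balance optimal.  v2: adds low damage and
    turnover markers (CK, haptoglobin, reticulocytes).  v3: adds high aerobic
    and immune capacity.  v4: metabolic directions (positive energy balance
    good, catabolic state bad) on top of v1.
    """
    v1 = {"ox_pc1": LOW, "ox_pc2": LOW}
    v2 = dict(v1, creatine_kinase=LOW, haptoglobin=LOW, reticulocytes=LOW)
    v3 = dict(v2, hematocrit=HIGH, hemoglobin=HIGH, nab_pc1=HIGH)
    v4 = dict(v1, triglycerides=HIGH, nefa=LOW, uric_acid=LOW,
              corticosterone=LOW)
    return [
        CentroidSpec("v0", {}),
        CentroidSpec("v1", v1),
        CentroidSpec("v2", v2),
        CentroidSpec("v3", v3),
        CentroidSpec("v4", v4),
    ]


def random_centroid_spec(subset, seed: int, label: str = "v5") -> CentroidSpec:
    """One random MEAN/HIGH/LOW draw per biomarker (the stochastic version)."""
    rng = np.random.default_rng(seed)
    options = (MEAN, HIGH, LOW)
    return CentroidSpec(label, {b: options[rng.integers(3)] for b in subset})


def build_centroid(panel: StandardizedPanel, spec: CentroidSpec,
                   subset=None) -> pd.Series:
    """Centroid on the z scale: 0 / +offset_sd / -offset_sd per biomarker."""
    cols = list(panel.values.columns) if subset is None else list(subset)
    spec.validate(cols)
    vals = {}
    for b in cols:
        choice = spec.choice.get(b, MEAN)
        vals[b] = {MEAN: 0.0, HIGH: spec.offset_sd, LOW: -spec.offset_sd}[choice]
    return pd.Series(vals, name=spec.label)


def mahalanobis(obs, centroid, covariance) -> float:
    """sqrt((x - mu)' S^{-1} (x - mu)); S must be symmetric positive-definite."""
    x = np.asarray(obs, dtype=float)
    mu = np.asarray(centroid, dtype=float)
    S = np.asarray(covariance, dtype=float)
    d = x - mu
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "covariance is singular or not positive-definite; use the "
            "'shrinkage' covariance policy"
        ) from err
    w = np.linalg.solve(L, d)
    return float(np.sqrt(w @ w))


def _shrink(S: np.ndarray, max_condition: float = 1e6) -> tuple[np.ndarray, float]:
    """Smallest diagonal shrinkage weight bounding the condition number."""
    target = np.diag(np.diag(S))
    for w in np.linspace(0.0, 1.0, 101):
        Sw = (1 - w) * S + w * target
        if np.linalg.cond(Sw) < max_condition:
            return Sw, float(w)
    return target, 1.0


def pooled_covariance(z: pd.DataFrame, policy: str = "sample") -> tuple[pd.DataFrame, float, float]:
    """Covariance over complete standardized rows, pooled across cells."""
    S = np.cov(z.to_numpy(dtype=float), rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    weight = 0.0
    if policy == "shrinkage":
        S, weight = _shrink(S)
    elif policy != "sample":
        raise ValueError(f"unknown covariance policy {policy!r}")
    cond = float(np.linalg.cond(S))
    return pd.DataFrame(S, index=z.columns, columns=z.columns), cond, weight


def score_dm(panel: StandardizedPanel, config: DMConfig,
             seed: int | None = None) -> DMScore:
    """Score all complete-case rows of the standardized panel under a config.

    Rows missing any active-subset variable are dropped and reported.  For the
    random version the per-biomarker choices are drawn once from the seed and
    recorded on the returned config.
    """
    subset = config.active_subset
    missing_cols = [c for c in subset if c not in panel.values.columns]
    if missing_cols:
        raise ValueError(f"panel lacks variables: {missing_cols}")

    spec = config.spec
    if spec.label == "v5" and not spec.choice:
        if seed is None:
            raise ValueError("the random centroid version needs a seed")
        spec = random_centroid_spec(subset, seed)
        config = replace(config, spec=spec)

    z = panel.values[subset]
    complete = z.dropna()
    dropped = sorted(set(z.index) - set(complete.index))
    p = len(subset)
    if len(complete) < p + 2:
        raise ValueError(
            f"only {len(complete)} complete rows for {p} variables; "
            "covariance would be unstable"
        )

    S, cond, weight = pooled_covariance(complete, config.covariance_policy)
    mu = build_centroid(panel, spec, subset)
    try:
        L = np.linalg.cholesky(S.to_numpy())
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "sample covariance is singular; use the 'shrinkage' policy"
        ) from err
    d = complete.to_numpy(dtype=float) - mu.to_numpy()
    w = np.linalg.solve(L, d.T)
    scores = pd.Series(np.sqrt((w**2).sum(axis=0)), index=complete.index,
                       name=config.label)
    return DMScore(scores, mu, S, panel.meta.loc[complete.index].copy(),
                   dropped, config, cond, weight)


def dm_sensitivity(panel: StandardizedPanel, configs,
                   seed: int | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation of DM versions on shared complete cases."""
    configs = list(configs)
    if len(configs) < 2:
        raise ValueError("need at least two DM configurations")
    scored = [score_dm(panel, c, seed=seed) for c in configs]
    shared = scored[0].scores.index
    for s in scored[1:]:
        shared = shared.intersection(s.scores.index)
    if len(shared) == 0:
        raise ValueError("no rows are complete under every configuration")
    mat = np.column_stack([s.scores.loc[shared].to_numpy() for s in scored])
    corr = np.corrcoef(mat, rowvar=False)
    labels = [s.config.label for s in scored]
    return pd.DataFrame(np.atleast_2d(corr), index=labels, columns=labels)
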