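"""Seeded synthetic cohorts of breeding female starlings.

The generator emulates the data structure of a two-year, two-stage
(repeated-measures) field study of female European starlings: each female is
blood-sampled during incubation and, when recaptured, during chick-rearing of
her first (and occasionally second) brood, in one or two seasons.  Each sample
carries a panel of physiological biomarkers spanning four functional
components (aerobic capacity, oxidative stress / muscle damage, intermediary
metabolism and energy supply, immune function), plus body mass, chick-rearing
wing area, nest-visit counts, and per-season reproductive outcomes.

Biomarker values follow a variance-components model: for female i in
year-stage cell (y, s),

    x = mean[y, s] + a_i * sd[y, s] * sqrt(icc) + e * sd[y, s] * sqrt(1 - icc)

where a_i is a per-female standard-normal draw shared across all of her
samples (so ``icc`` is the between-individual variance fraction, i.e. the
repeatability the analysis should recover) and e is a row-level draw from a
multivariate normal with the configured residual cross-correlation.

Outcomes are drawn from simple families (Gaussian, Poisson count, Bernoulli)
and are independent of physiology unless an ``effect_map`` plants effects on
their linear predictors via the female's standardized chick-rearing biomarker
values.  ``null_cohort`` forces the global null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BiomarkerSpec",
    "OutcomeSpec",
    "CohortConfig",
    "default_biomarkers",
    "default_outcomes",
    "default_config",
    "generate_cohort",
    "null_cohort",
    "write_cohort",
    "read_cohort",
    "INCUBATION",
    "CHICK_REARING",
]

INCUBATION = "incubation"
CHICK_REARING = "chick_rearing"

GROUPS = ("aerobic_capacity", "oxidative_stress", "metabolism_energy", "immune")
TRANSFORMS = ("none", "log", "sqrt")
OPTIMA = ("mean", "high", "low", "unknown")
OUTCOME_FAMILIES = ("gaussian", "poisson_count", "bernoulli")

#: outcomes drawn directly from OutcomeSpec families; totals are derived sums
DRAWN_OUTCOMES = (
    "visit_rate",
    "brood_size_d6",
    "bsf1",
    "mean_fledging_mass_b1",
    "bsf2",
    "mean_fledging_mass_b2",
    "second_brood",
    "returned_year2",
    "lay_date_year2",
)

DERIVED_OUTCOMES = (
    "total_fledged_year",
    "total_fledgling_mass_year",
    "bsf1_year2",
    "fledglings_2yr",
)

OUTCOME_COLUMNS = DRAWN_OUTCOMES + DERIVED_OUTCOMES


@dataclass
class BiomarkerSpec:
    """Distributional description of one biomarker across year-stage cells."""

    name: str
    group: str
    mean_by_cell: dict
    sd_by_cell: dict
    icc: float
    transform: str = "none"
    missing_rate: float = 0.0
    optimum_hypothesis: str = "mean"
    lower_bound: float | None = None   # assay floor; draws are clipped here

    def validate(self, cells) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"{self.name}: unknown group {self.group!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"{self.name}: unknown transform {self.transform!r}")
        if self.optimum_hypothesis not in OPTIMA:
            raise ValueError(f"{self.name}: unknown optimum {self.optimum_hypothesis!r}")
        if not 0.0 <= self.icc <= 1.0:
            raise ValueError(f"{self.name}: icc {self.icc} outside [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"{self.name}: missing_rate outside [0, 1]")
        for cell in cells:
            if cell not in self.mean_by_cell or cell not in self.sd_by_cell:
                raise ValueError(f"{self.name}: cell {cell} missing from mean/sd maps")
            if not self.sd_by_cell[cell] > 0:
                raise ValueError(f"{self.name}: sd for cell {cell} not positive")


@dataclass
class OutcomeSpec:
    family: str
    mean: float          # Gaussian mean / Poisson rate / Bernoulli probability
    sd: float | None = None

    def validate(self, name: str) -> None:
        if self.family not in OUTCOME_FAMILIES:
            raise ValueError(f"{name}: outcome family {self.family!r} not one of {OUTCOME_FAMILIES}")
        if self.family == "gaussian" and (self.sd is None or self.sd <= 0):
            raise ValueError(f"{name}: gaussian outcome needs positive sd")
        if self.family == "bernoulli" and not 0 <= self.mean <= 1:
            raise ValueError(f"{name}: bernoulli probability outside [0, 1]")
        if self.family == "poisson_count" and self.mean <= 0:
            raise ValueError(f"{name}: poisson rate must be positive")


def _cells(base, stage=0.0, year=0.0, interaction=0.0, years=(2013, 2014)):
    """Additive (+ optional interaction) means over the 2 x 2 design."""
    y0, y1 = years
    return {
        (y0, INCUBATION): base,
        (y0, CHICK_REARING): base + stage,
        (y1, INCUBATION): base + year,
        (y1, CHICK_REARING): base + year + stage + interaction,
    }


def _const_sd(sd, years=(2013, 2014)):
    return {(y, s): sd for y in years for s in (INCUBATION, CHICK_REARING)}


def default_biomarkers(years=(2013, 2014)) -> list[BiomarkerSpec]:
    """The 14 raw assay columns (12 single markers + agglutination & lysis).

    Cell means for reticulocytes, OXY and glucose follow the published
    year-by-stage patterns; remaining means/SDs are plausible round values
    for breeding female starlings (raw per-cell tables are not deposited).
    """
    y0, y1 = years
    mk = lambda **kw: _cells(years=years, **kw)
    sd = lambda s: _const_sd(s, years)
    return [
        BiomarkerSpec("hematocrit", "aerobic_capacity", mk(base=45.0, stage=-1.2),
                      sd(3.0), icc=0.30, lower_bound=0.0),
        BiomarkerSpec("hemoglobin", "aerobic_capacity", mk(base=15.2, stage=0.5, year=0.8),
                      sd(1.2), icc=0.25, lower_bound=0.0),
        BiomarkerSpec(
            "reticulocytes", "aerobic_capacity",
            {(y0, INCUBATION): 15.6, (y0, CHICK_REARING): 8.2,
             (y1, INCUBATION): 8.7, (y1, CHICK_REARING): 7.3},
            {(y0, INCUBATION): 6.1, (y0, CHICK_REARING): 5.1,
             (y1, INCUBATION): 5.9, (y1, CHICK_REARING): 2.5},
            icc=0.15, transform="sqrt", missing_rate=0.30,
            optimum_hypothesis="low", lower_bound=0.0),
        BiomarkerSpec("corticosterone", "aerobic_capacity", mk(base=12.0),
                      sd(2.4), icc=0.55, transform="log", missing_rate=0.03,
                      optimum_hypothesis="low", lower_bound=0.1),
        BiomarkerSpec("creatine_kinase", "oxidative_stress",
                      mk(base=900.0, stage=-150.0, year=-100.0),
                      sd(170.0), icc=0.30, transform="log", missing_rate=0.03,
                      optimum_hypothesis="low", lower_bound=1.0),
        BiomarkerSpec("oxy", "oxidative_stress",
                      {(y0, INCUBATION): 254.4, (y0, CHICK_REARING): 271.1,
                       (y1, INCUBATION): 167.6, (y1, CHICK_REARING): 232.9},
                      sd(45.0), icc=0.30, missing_rate=0.03,
                      optimum_hypothesis="unknown", lower_bound=0.0),
        BiomarkerSpec("droms", "oxidative_stress", mk(base=27.0, stage=-2.0, year=-4.0),
                      sd(4.5), icc=0.20, transform="log", missing_rate=0.03,
                      optimum_hypothesis="low", lower_bound=0.5),
        BiomarkerSpec("nefa", "metabolism_energy", mk(base=0.60, stage=0.18),
                      sd(0.16), icc=0.15, missing_rate=0.03,
                      optimum_hypothesis="low", lower_bound=0.0),
        BiomarkerSpec("triglycerides", "metabolism_energy", mk(base=1.6, stage=0.5),
                      sd(0.32), icc=0.15, transform="log", missing_rate=0.03,
                      optimum_hypothesis="high", lower_bound=0.05),
        BiomarkerSpec("glucose", "metabolism_energy",
                      {(y0, INCUBATION): 11.5, (y0, CHICK_REARING): 10.6,
                       (y1, INCUBATION): 10.6, (y1, CHICK_REARING): 11.4},
                      sd(1.1), icc=0.20, lower_bound=0.0),
        BiomarkerSpec("uric_acid", "metabolism_energy", mk(base=0.48, stage=0.14, year=0.05),
                      sd(0.12), icc=0.15, missing_rate=0.03,
                      optimum_hypothesis="unknown", lower_bound=0.0),
        BiomarkerSpec("haptoglobin", "immune", mk(base=0.30, year=0.08),
                      sd(0.06), icc=0.25, transform="log", missing_rate=0.03,
                      optimum_hypothesis="low", lower_bound=0.01),
        BiomarkerSpec("agglutination", "immune", mk(base=8.0), sd(2.0),
                      icc=0.30, missing_rate=0.05,
                      optimum_hypothesis="high", lower_bound=0.0),
        BiomarkerSpec("lysis", "immune", mk(base=4.0), sd(1.2),
                      icc=0.30, missing_rate=0.05,
                      optimum_hypothesis="high", lower_bound=0.0),
    ]


def default_mass_spec(years=(2013, 2014)) -> BiomarkerSpec:
    return BiomarkerSpec("body_mass", "metabolism_energy",
                         _cells(base=76.0, stage=-2.5, years=years),
                         _const_sd(4.0, years), icc=0.50, lower_bound=40.0)


def default_outcomes() -> dict:
    """Per-season outcome families; rates/means typical of starling broods."""
    return {
        "visit_rate": OutcomeSpec("gaussian", 12.0, 3.0),        # visits / h
        "brood_size_d6": OutcomeSpec("poisson_count", 5.2),
        "bsf1": OutcomeSpec("poisson_count", 4.2),
        "mean_fledging_mass_b1": OutcomeSpec("gaussian", 70.0, 5.0),  # g
        "bsf2": OutcomeSpec("poisson_count", 3.0),
        "mean_fledging_mass_b2": OutcomeSpec("gaussian", 65.0, 5.0),
        "lay_date_year2": OutcomeSpec("gaussian", 105.0, 7.0),   # day of year
    }


def _default_cross_correlation(names: list[str]) -> np.ndarray:
    """Near-diagonal residual correlation with a few physiological pairs."""
    R = np.eye(len(names))
    idx = {n: i for i, n in enumerate(names)}
    for a, b, r in [("hematocrit", "hemoglobin", 0.5),
                    ("oxy", "droms", 0.3),
                    ("agglutination", "lysis", 0.3),
                    ("droms", "uric_acid", -0.2)]:
        if a in idx and b in idx:
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return R


@dataclass
class CohortConfig:
    n_females: int = 93
    years: tuple = (2013, 2014)
    stages: tuple = (INCUBATION, CHICK_REARING)
    biomarkers: list = field(default_factory=default_biomarkers)
    mass_spec: BiomarkerSpec = field(default_factory=default_mass_spec)
    cross_correlation: np.ndarray | None = None
    effect_map: list = field(default_factory=list)   # (biomarker, outcome, effect)
    outcome_specs: dict = field(default_factory=default_outcomes)
    return_rate: float = 0.35
    second_brood_rate: float = 0.35
    cr_recapture_rate: float = 0.50
    brood2_sample_rate: float = 0.25
    first_year_fraction: float = 0.60
    observation_hours: float = 1.5
    male_visit_rate: float = 10.0     # visits / h
    known_visit_fraction: float = 0.90
    wing_area_mean: float = 250.0     # cm^2
    wing_area_sd: float = 15.0
    seed: int = 0

    @property
    def biomarker_names(self) -> list[str]:
        return [b.name for b in self.biomarkers]

    def resolved_cross_correlation(self) -> np.ndarray:
        if self.cross_correlation is None:
            return _default_cross_correlation(self.biomarker_names)
        return np.asarray(self.cross_correlation, dtype=float)

    def validate(self) -> None:
        if self.n_females <= 0:
            raise ValueError("n_females must be positive")
        if len(self.stages) != 2:
            raise ValueError("exactly two breeding stages expected")
        cells = [(y, s) for y in self.years for s in self.stages]
        for spec in self.biomarkers + [self.mass_spec]:
            spec.validate(cells)
        for name, spec in self.outcome_specs.items():
            spec.validate(name)
        for rate in (self.return_rate, self.second_brood_rate,
                     self.cr_recapture_rate, self.brood2_sample_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        R = self.resolved_cross_correlation()
        k = len(self.biomarkers)
        if R.shape != (k, k):
            raise ValueError(f"cross_correlation must be {k}x{k}, got {R.shape}")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("cross_correlation matrix is not symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("cross_correlation diagonal must be 1")
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-8:
            raise ValueError(
                f"cross_correlation is not positive semi-definite: "
                f"smallest eigenvalue {eig.min():.3e}"
            )
        known = set(self.biomarker_names)
        for bio, out, _ in self.effect_map:
            if bio not in known:
                raise ValueError(f"effect_map biomarker {bio!r} not in panel")
            if out not in DRAWN_OUTCOMES:
                raise ValueError(f"effect_map outcome {out!r} is not a drawn outcome")


def default_config(**overrides) -> CohortConfig:
    return replace(CohortConfig(), **overrides) if overrides else CohortConfig()


def _draw_outcome(rng, spec: OutcomeSpec, shift: np.ndarray):
    """Draw from the family with the linear predictor shifted by ``shift``."""
    n = shift.shape[0]
    if spec.family == "gaussian":
        return spec.mean + shift + rng.normal(0.0, spec.sd, n)
    if spec.family == "poisson_count":
        return rng.poisson(np.exp(np.log(spec.mean) + shift)).astype(float)
    # bernoulli on the logit scale
    base = np.log(spec.mean / (1.0 - spec.mean)) if 0 < spec.mean < 1 else (
        30.0 if spec.mean >= 1 else -30.0)
    p = 1.0 / (1.0 + np.exp(-(base + shift)))
    return (rng.random(n) < p).astype(float)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate one cohort; deterministic given (config, seed).

    Returns a long-format table: one row per female x year x stage x brood
    sample, with biomarker columns, body mass, chick-rearing wing area, visit
    counts, and the season's outcome columns repeated on every row of that
    female-year (outcomes come from nest monitoring and exist whether or not
    the female was recaptured for blood sampling).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    y0, y1 = config.years
    names = config.biomarker_names
    B = len(names)

    # --- study structure -------------------------------------------------
    females = [f"F{i + 1:03d}" for i in range(config.n_females)]
    n_first = int(round(config.first_year_fraction * config.n_females))
    start_year = {f: (y0 if i < n_first else y1) for i, f in enumerate(females)}
    returned = {f: bool(rng.random() < config.return_rate) for f in females}

    female_years: list[tuple[str, int]] = []
    for f in females:
        female_years.append((f, start_year[f]))
        if start_year[f] == y0 and returned[f]:
            female_years.append((f, y1))

    second_brood = {fy: bool(rng.random() < config.second_brood_rate)
                    for fy in female_years}
    cr_sampled = {fy: bool(rng.random() < config.cr_recapture_rate)
                  for fy in female_years}
    b2_sampled = {fy: second_brood[fy] and bool(rng.random() < config.brood2_sample_rate)
                  for fy in female_years}

    # internal row list; chick-rearing brood-1 rows always generated so that
    # planted effects can use the female's (possibly unobserved) CR physiology
    rows = []   # (female, year, stage, brood, sampled)
    for fy in female_years:
        f, y = fy
        rows.append((f, y, INCUBATION, 1, True))
        rows.append((f, y, CHICK_REARING, 1, cr_sampled[fy]))
        if b2_sampled[fy]:
            rows.append((f, y, CHICK_REARING, 2, True))
    R = len(rows)

    # --- biomarker values -------------------------------------------------
    a = rng.standard_normal((config.n_females, B))            # per-female
    L = np.linalg.cholesky(
        config.resolved_cross_correlation() + 1e-10 * np.eye(B))
    e = rng.standard_normal((R, B)) @ L.T                     # per-row residual
    fidx = {f: i for i, f in enumerate(females)}

    means = np.empty((R, B))
    sds = np.empty((R, B))
    for j, spec in enumerate(config.biomarkers):
        for i, (f, y, s, _, _) in enumerate(rows):
            means[i, j] = spec.mean_by_cell[(y, s)]
            sds[i, j] = spec.sd_by_cell[(y, s)]
    icc = np.array([b.icc for b in config.biomarkers])
    arow = a[[fidx[r[0]] for r in rows]]
    values = means + arow * sds * np.sqrt(icc) + e * sds * np.sqrt(1.0 - icc)
    for j, spec in enumerate(config.biomarkers):
        if spec.lower_bound is not None:
            values[:, j] = np.maximum(values[:, j], spec.lower_bound)

    # body mass: same variance-components model, own spec
    ms = config.mass_spec
    a_mass = rng.standard_normal(config.n_females)
    e_mass = rng.standard_normal(R)
    m_mean = np.array([ms.mean_by_cell[(y, s)] for _, y, s, _, _ in rows])
    m_sd = np.array([ms.sd_by_cell[(y, s)] for _, y, s, _, _ in rows])
    mass = m_mean + a_mass[[fidx[r[0]] for r in rows]] * m_sd * np.sqrt(ms.icc) \
        + e_mass * m_sd * np.sqrt(1.0 - ms.icc)
    if ms.lower_bound is not None:
        mass = np.maximum(mass, ms.lower_bound)

    wing = np.where(
        np.array([r[2] == CHICK_REARING for r in rows]),
        rng.normal(config.wing_area_mean, config.wing_area_sd, R),
        np.nan,
    )

    # --- planted effects: standardized CR brood-1 physiology per female-year
    cr1 = {(r[0], r[1]): i for i, r in enumerate(rows)
           if r[2] == CHICK_REARING and r[3] == 1}
    z_cr = np.zeros((len(female_years), B))
    for k, fy in enumerate(female_years):
        i = cr1[fy]
        z_cr[k] = (values[i] - means[i]) / sds[i]

    shifts = {out: np.zeros(len(female_years)) for out in DRAWN_OUTCOMES}
    for bio, out, eff in config.effect_map:
        shifts[out] += eff * z_cr[:, names.index(bio)]

    # --- outcomes per female-year ----------------------------------------
    nfy = len(female_years)
    out: dict[str, np.ndarray] = {}
    specs = config.outcome_specs
    for name in ("visit_rate", "brood_size_d6", "bsf1", "mean_fledging_mass_b1",
                 "bsf2", "mean_fledging_mass_b2", "lay_date_year2"):
        out[name] = _draw_outcome(rng, specs[name], shifts[name])
    out["second_brood"] = np.array(
        [float(second_brood[fy]) for fy in female_years])
    # a planted effect on second_brood replaces the structural indicator
    if np.any(shifts["second_brood"] != 0.0):
        out["second_brood"] = _draw_outcome(
            rng, OutcomeSpec("bernoulli", config.second_brood_rate),
            shifts["second_brood"])
    out["returned_year2"] = np.array([float(returned[f]) for f, _ in female_years])
    if np.any(shifts["returned_year2"] != 0.0):
        out["returned_year2"] = _draw_outcome(
            rng, OutcomeSpec("bernoulli", config.return_rate),
            shifts["returned_year2"])

    # conditioning: brood-2 outcomes exist only when a second brood happened;
    # first-brood fledging mass undefined for total failures
    sb = out["second_brood"] > 0
    out["bsf2"] = np.where(sb, out["bsf2"], np.nan)
    out["mean_fledging_mass_b2"] = np.where(sb, out["mean_fledging_mass_b2"], np.nan)
    out["mean_fledging_mass_b1"] = np.where(out["bsf1"] > 0,
                                            out["mean_fledging_mass_b1"], np.nan)

    bsf2_filled = np.where(sb, out["bsf2"], 0.0)
    out["total_fledged_year"] = out["bsf1"] + bsf2_filled
    out["total_fledgling_mass_year"] = (
        out["bsf1"] * np.nan_to_num(out["mean_fledging_mass_b1"])
        + bsf2_filled * np.nan_to_num(out["mean_fledging_mass_b2"]))

    # next-year links: a returning first-year female's year-2 season supplies
    # her bsf1_year2; returning second-year females are monitored only
    fy_index = {fy: k for k, fy in enumerate(female_years)}
    bsf1_y2 = np.full(nfy, np.nan)
    lay_y2 = np.full(nfy, np.nan)
    fledg2 = np.full(nfy, np.nan)
    for k, (f, y) in enumerate(female_years):
        if y != y0:
            out["returned_year2"][k] = (out["returned_year2"][k]
                                        if start_year[f] == y1 else np.nan)
            if start_year[f] == y1 and out["returned_year2"][k] == 1.0:
                bsf1_y2[k] = rng.poisson(specs["bsf1"].mean)
                lay_y2[k] = rng.normal(specs["lay_date_year2"].mean,
                                       specs["lay_date_year2"].sd)
                fledg2[k] = out["total_fledged_year"][k] + bsf1_y2[k]
            else:
                fledg2[k] = np.nan
            continue
        if returned[f]:
            k2 = fy_index[(f, y1)]
            bsf1_y2[k] = out["bsf1"][k2]
            lay_y2[k] = out["lay_date_year2"][k]
            fledg2[k] = (out["total_fledged_year"][k]
                         + out["total_fledged_year"][k2])
        else:
            fledg2[k] = out["total_fledged_year"][k]
    out["bsf1_year2"] = bsf1_y2
    out["lay_date_year2"] = lay_y2
    out["fledglings_2yr"] = fledg2

    # --- nest-visit counts (chick-rearing brood-1 observation sessions) ---
    hours = config.observation_hours
    f_rate = np.maximum(out["visit_rate"], 0.5)
    f_count = rng.poisson(f_rate * hours)
    m_count = rng.poisson(config.male_visit_rate * hours, nfy)
    f_known = rng.binomial(f_count, config.known_visit_fraction)
    m_known = rng.binomial(m_count, config.known_visit_fraction)
    unknown = (f_count - f_known) + (m_count - m_known)

    # --- missingness (emitted rows only) ----------------------------------
    miss = rng.random((R, B))
    for j, spec in enumerate(config.biomarkers):
        values[miss[:, j] < spec.missing_rate, j] = np.nan

    # --- assemble ----------------------------------------------------------
    sampled = np.array([r[4] for r in rows])
    recs = {
        "female_id": [r[0] for r in rows],
        "year": [r[1] for r in rows],
        "stage": [r[2] for r in rows],
        "brood": [r[3] for r in rows],
        "body_mass": mass,
        "wing_area": wing,
    }
    for j, name in enumerate(names):
        recs[name] = values[:, j]
    fy_of_row = [fy_index[(r[0], r[1])] for r in rows]
    for name in OUTCOME_COLUMNS:
        if name == "visit_rate":
            continue
        recs[name] = out[name][fy_of_row]
    recs["female_visits_known"] = f_known[fy_of_row].astype(float)
    recs["male_visits_known"] = m_known[fy_of_row].astype(float)
    recs["visits_unknown"] = unknown[fy_of_row].astype(float)
    recs["observation_hours"] = np.full(R, hours)

    df = pd.DataFrame(recs)
    return df.loc[sampled].reset_index(drop=True)


def null_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Cohort under the global null: effect_map emptied before generation."""
    return generate_cohort(replace(config, effect_map=[]), seed=seed)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Long-format CSV dialect: UTF-8, comma, header, empty string = missing."""
    df.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df
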