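"""Synthetic herd histories and measurement records.

The generator is the statistical twin of the analysis model: multi-decadal
population trajectories with sparse, noisy surveys (some lacking
confidence intervals), and individual morphometric records whose year
means follow trait = alpha + beta * popsize/10,000 with i.i.d. Normal
residuals, optional season- or phase-specific coefficients and an
optional polynomial date effect. A registry of presets encodes one
generating scenario per published herd x age-class x trait relationship,
using the published posterior estimates as generating values, so
parameter-recovery experiments run against realistic conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .trajectory import SurveyEstimate

__all__ = [
    "TrajectoryScenario", "GeneratingParams", "simulate_trajectory",
    "simulate_individuals", "simulate_conversion_pairs",
    "scenario_from_table2", "preset_info", "list_presets",
    "write_survey_csv", "write_records_csv",
]

SEASON_MONTHS = {
    "late_winter": (1, 2, 3, 4),
    "summer": (5, 6, 7, 8),
    "early_winter": (9, 10, 11, 12),
}

SHAPES = ("growth", "decline", "peak", "trough")


@dataclass(frozen=True)
class TrajectoryScenario:
    """A herd history: anchor sizes, shape, and the survey schedule.

    ``shape`` is one of growth, decline, peak (growth then decline) or
    trough (decline then growth); ``peak_size`` is the interior extremum
    for the last two shapes. Interpolation between anchors is log-linear:
    population change is multiplicative.
    """

    years: tuple
    shape: str
    start_size: float
    end_size: float
    peak_size: float | None = None
    peak_year: int | None = None
    survey_years: tuple = ()
    rel_error: float = 0.10
    ci_level: int = 95
    missing_ci_fraction: float = 0.5
    herd: str = "sim"
    seed: int = 0

    def __post_init__(self):
        y0, y1 = self.years
        if y1 <= y0:
            raise ValueError("years must be an increasing range")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        for s in (self.start_size, self.end_size,
                  *([self.peak_size] if self.peak_size is not None else [])):
            if s <= 0:
                raise ValueError("population sizes must be positive")
        if not (0.0 <= self.rel_error < 1.0):
            raise ValueError("rel_error must be in [0, 1)")
        if self.survey_years and not set(self.survey_years) <= set(
                range(y0, y1 + 1)):
            raise ValueError("survey_years must lie within years")

    @property
    def year_range(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)


@dataclass(frozen=True)
class GeneratingParams:
    """Generators for the trait model: alpha, beta, sigma and structure."""

    alpha: float
    beta: float
    sigma: float
    n_per_year: int
    trait: str
    age_class: str = "adult"
    herd: str = "sim"
    season_effects: dict | None = None   # season -> (alpha, beta)
    date_effect: tuple | None = None     # polynomial coefficients in day
    phase_betas: dict | None = None      # "growth"/"decline" -> beta
    repeat_fraction: float = 0.10

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_per_year < 1:
            raise ValueError("n_per_year must be at least 1")
        betas = [self.beta]
        if self.phase_betas:
            betas += list(self.phase_betas.values())
        if self.season_effects:
            betas += [b for _, b in self.season_effects.values()]
        if any(abs(b) > 1 for b in betas):
            raise ValueError("beta outside prior support [-1, 1]")


def _log_linear(years, anchors):
    """Piecewise log-linear interpolation through (year, size) anchors."""
    ay = np.array([a[0] for a in anchors], dtype=float)
    av = np.log([a[1] for a in anchors])
    return np.exp(np.interp(np.asarray(years, dtype=float), ay, av))


def simulate_trajectory(scenario: TrajectoryScenario
                        ) -> tuple[pd.Series, list[SurveyEstimate]]:
    """True annual sizes plus noisy surveys for a scenario.

    Survey estimates are Normal(true, rel_error * true / 1.96) truncated
    positive — rel_error plays the role of the 95% half-width ratio. A
    ``missing_ci_fraction`` of surveys carry no interval; the rest get
    the symmetric estimate*(1 +/- rel_error) bounds. Deterministic given
    the scenario seed.
    """
    if not scenario.survey_years:
        raise ValueError("no surveys: survey_years is empty")
    y0, y1 = scenario.years
    if scenario.shape in ("peak", "trough"):
        if scenario.peak_size is None:
            raise ValueError(f"{scenario.shape} shape needs peak_size")
        py = scenario.peak_year if scenario.peak_year is not None \
            else (y0 + y1) // 2
        anchors = [(y0, scenario.start_size), (py, scenario.peak_size),
                   (y1, scenario.end_size)]
    else:
        anchors = [(y0, scenario.start_size), (y1, scenario.end_size)]
    years = scenario.year_range
    true_sizes = pd.Series(_log_linear(years, anchors), index=years,
                           name="true_size")

    rng = np.random.default_rng(scenario.seed)
    surveys = []
    survey_years = sorted(scenario.survey_years)
    no_ci = rng.random(len(survey_years)) < scenario.missing_ci_fraction
    if no_ci.all():
        # at least one survey must keep its interval or the herd mean
        # error is undefined; real series always retain some
        no_ci[-1] = False
    for year, skip_ci in zip(survey_years, no_ci):
        true = float(true_sizes[year])
        sd = scenario.rel_error * true / 1.96
        est = true if sd == 0 else -1.0
        while est <= 0:
            est = rng.normal(true, sd)
        if skip_ci and scenario.rel_error > 0:
            lci = uci = ci_level = None
        else:
            lci = est * (1.0 - scenario.rel_error)
            uci = est * (1.0 + scenario.rel_error)
            ci_level = scenario.ci_level
        surveys.append(SurveyEstimate(scenario.herd, int(year), est,
                                      lci, uci, ci_level, "field"))
    return true_sizes, surveys


def _phases_from_sizes(true_sizes: pd.Series) -> pd.Series:
    d = np.diff(true_sizes.to_numpy())
    lab = np.where(d >= 0, "growth", "decline")
    lab = np.append(lab, lab[-1] if lab.size else "growth")
    return pd.Series(lab, index=true_sizes.index)


def _blank_record(herd, ind_id, sex, age_months, cohort, date):
    return {"individual_id": ind_id, "herd": herd, "sex": sex,
            "age_months": age_months, "cohort_year": cohort, "date": date,
            "hfl_cm": np.nan, "metatarsus_cm": np.nan,
            "mass_live_kg": np.nan, "mass_evisc_kg": np.nan,
            "fat_index": np.nan}


def _measurement_plan(trait, age_class, gen_year, month):
    """(cohort_year, measurement date pieces, age_months) for one record.

    ``gen_year`` is the population year whose size drives the trait
    (i.e. the intended link year); cohorts and dates are laid out so the
    harmonization link rules map the record back to it. Individuals are
    born June 1 of their cohort year.
    """
    if age_class == "newborn":
        return gen_year, (gen_year, 6), 0.5
    if trait == "hfl":
        cohort = gen_year - 1
        if age_class == "adult":
            return cohort, (cohort + 2, 12), 30.0  # 2.5 y: adult for skeleton
        return cohort, (cohort + 1, 12), 18.0      # yearling
    # mass / fat: link year is the measurement year
    if age_class == "yearling":
        cohort = gen_year - 1 if month >= 7 else gen_year - 2
    else:
        cohort = gen_year - 4
    return cohort, (gen_year, month), (gen_year - cohort) * 12 + (month - 6)


def simulate_individuals(true_sizes: pd.Series, params: GeneratingParams,
                         seed: int = 0) -> pd.DataFrame:
    """Individual measurement records generated under the trait model.

    Each record's trait value is alpha(+season) + beta(+phase/season) *
    size/10,000 + date_polynomial(day) + Normal(0, sigma) noise, where
    size is the true population size of the record's link year. A
    ``repeat_fraction`` of yearlings/adults are measured again the
    following year to exercise repeat-measurement handling. Deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    phases = _phases_from_sizes(true_sizes) if params.phase_betas else None
    seasons = list(params.season_effects) if params.season_effects else [None]
    rows = []

    def trait_value(gen_year, season, day):
        x = float(true_sizes[gen_year]) / 10_000.0
        if season is not None and params.season_effects:
            a, b = params.season_effects[season]
        else:
            a = params.alpha
            b = (params.phase_betas[phases[gen_year]]
                 if params.phase_betas else params.beta)
        val = a + b * x
        if params.date_effect is not None:
            val += float(np.polynomial.polynomial.polyval(
                day, params.date_effect))
        return val + (rng.normal(0.0, params.sigma) if params.sigma else 0.0)

    for gen_year in true_sizes.index:
        gen_year = int(gen_year)
        for i in range(params.n_per_year):
            season = seasons[i % len(seasons)]
            if params.age_class == "newborn":
                month = 6
            elif season is not None:
                month = int(rng.choice(SEASON_MONTHS[season]))
            else:
                month = int(rng.integers(1, 13))
            day_of_month = int(rng.integers(1, 29))
            cohort, (my, mm), age_months = _measurement_plan(
                params.trait, params.age_class, gen_year, month)
            date = pd.Timestamp(my, mm, day_of_month)
            sex = "F" if params.age_class != "newborn" else \
                ("F" if rng.random() < 0.5 else "M")
            rec = _blank_record(params.herd,
                                f"{params.herd}-{gen_year}-{i:03d}",
                                sex, age_months, cohort, date)
            value = trait_value(gen_year, season, date.dayofyear)
            col = {"hfl": "hfl_cm", "mass": "mass_live_kg",
                   "fat": "fat_index"}[params.trait]
            rec[col] = value
            rows.append(rec)
            # occasional recapture one year later
            if (params.age_class != "newborn"
                    and gen_year + 1 in true_sizes.index
                    and rng.random() < params.repeat_fraction):
                rec2 = dict(rec)
                rec2["date"] = date + pd.DateOffset(years=1)
                rec2["age_months"] = age_months + 12.0
                link2 = gen_year if params.trait == "hfl" else gen_year + 1
                rec2[col] = trait_value(link2, season,
                                        rec2["date"].dayofyear)
                rows.append(rec2)
    df = pd.DataFrame(rows)
    df["date"] = pd.to_datetime(df["date"])
    return df


def simulate_conversion_pairs(n: int, kind: str, seed: int = 0,
                              n_years: int = 10, year_sd: float = 1.0,
                              resid_sd: float = 1.0,
                              age_offsets: dict | None = None
                              ) -> pd.DataFrame:
    """Paired calibration measurements from the retained conversion models.

    ``kind`` is "metatarsus" (x = metatarsus cm, y = hind foot cm;
    y = -3.17 + 1.50 x) or "eviscerated" (x = eviscerated kg, y = live
    kg; y = 13.33 + age_offset + 1.27 x). Noise = a year random intercept
    (sd ``year_sd``) plus i.i.d. residual (sd ``resid_sd``).
    """
    if n < 10:
        raise ValueError("insufficient calibration pairs (need >= 10)")
    if kind not in ("metatarsus", "eviscerated"):
        raise ValueError(f"unknown kind {kind!r}")
    rng = np.random.default_rng(seed)
    years = 1990 + rng.integers(0, n_years, n)
    year_effects = {y: rng.normal(0.0, year_sd)
                    for y in range(1990, 1990 + n_years)}
    u = np.array([year_effects[y] for y in years])
    sex = rng.choice(["F", "M"], n)
    age_class = rng.choice(["yearling", "adult"], n)
    if kind == "metatarsus":
        x = rng.normal(36.0, 3.0, n)
        y = -3.17 + 1.50 * x
    else:
        x = np.clip(rng.normal(55.0, 10.0, n), 15.0, None)
        offs = np.array([(age_offsets or {}).get(c, 0.0) for c in age_class])
        y = 13.33 + offs + 1.27 * x
    y = y + u + (rng.normal(0.0, resid_sd, n) if resid_sd else 0.0)
    return pd.DataFrame({"x": x, "y": y, "year": years, "sex": sex,
                         "age_class": age_class})


# ---------------------------------------------------------------------------
# preset registry


def _registry() -> dict:
    with resources.files("morphotrend").joinpath("presets.json").open() as fh:
        return json.load(fh)


def list_presets() -> list[str]:
    return sorted(_registry())


def preset_info(row_label: str) -> dict:
    reg = _registry()
    if row_label not in reg:
        raise KeyError(f"unknown preset {row_label!r}; available: "
                       f"{sorted(reg)}")
    return reg[row_label]


def scenario_from_table2(row_label: str, seed: int = 0
                         ) -> tuple[TrajectoryScenario, GeneratingParams]:
    """Generating scenario + parameters for one published relationship.

    The registry uses the published posterior estimates (alpha, beta,
    sigma) as generating values and a trajectory spanning the herd's
    measurement period.
    """
    p = preset_info(row_label)
    y0, y1 = p["years"]
    survey_years = tuple(range(y0, y1 + 1, p.get("survey_every", 2)))
    if y1 not in survey_years:
        survey_years = survey_years + (y1,)
    scenario = TrajectoryScenario(
        years=(y0, y1), shape=p["shape"], start_size=p["start_size"],
        end_size=p["end_size"], peak_size=p.get("peak_size"),
        peak_year=p.get("peak_year"), survey_years=survey_years,
        rel_error=p["rel_error"], herd=p["herd"], seed=seed)
    season_effects = ({k: tuple(v) for k, v in p["season_effects"].items()}
                      if "season_effects" in p else None)
    params = GeneratingParams(
        alpha=p.get("alpha", 0.0), beta=p.get("beta", 0.0),
        sigma=p["sigma"], n_per_year=p["n_per_year"], trait=p["trait"],
        age_class=p["age_class"], herd=p["herd"],
        season_effects=season_effects,
        phase_betas=p.get("phase_betas"))
    return scenario, params


# ---------------------------------------------------------------------------
# CSV writers


def write_survey_csv(surveys, path):
    pd.DataFrame(
        [{"herd": s.herd, "year": s.year, "estimate": s.estimate,
          "lci": s.lci, "uci": s.uci, "ci_level": s.ci_level,
          "source": s.source} for s in surveys]
    ).to_csv(path, index=False)


def write_records_csv(records: pd.DataFrame, path):
    records.to_csv(path, index=False)
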