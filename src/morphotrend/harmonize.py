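"""Convert, standardize, filter and link individual caribou measurements.

Raw capture records mix measurement protocols accumulated over three
decades: hind foot length measured directly or inferred from metatarsus
length, mass weighed live or after evisceration, dates scattered across
seasons. This module harmonizes them into analysis-ready trait
observations:

* unit conversions from the retained mixed-model calibrations
  (HFL = −3.17 + 1.50·META; live mass = 13.33 + Age + 1.27·eviscerated);
* age-class assignment (newborn <= 1 month, yearling 13-24 months,
  adult >= 25 months — >= 30 months for skeletal analyses);
* season assignment (late winter Jan–Apr, summer May–Aug, early winter
  Sep–Dec; newborns restricted to June);
* date standardization to the stratum's mean measurement day via a
  polynomial of ANOVA-selected order;
* ordered inclusion filters with a full accounting of removals;
* linkage of each observation to the population year its trait should
  reflect (cohort+1 for skeletal size, year of measurement for mass and
  fat, cohort year for newborns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.anova import anova_lm

from .trajectory import PopulationTrajectory

__all__ = [
    "HFL_INTERCEPT", "HFL_SLOPE", "MASS_INTERCEPT", "MASS_SLOPE",
    "PLAUSIBILITY", "FilterReport",
    "metatarsus_to_hfl", "eviscerated_to_live",
    "assign_age_class", "assign_season",
    "fit_date_polynomial", "standardize_to_mean_date",
    "apply_inclusion_filters", "population_link_year",
    "harmonize_records", "read_records_csv",
]

# retained calibration coefficients (year random effect at its zero mean)
HFL_INTERCEPT, HFL_SLOPE = -3.17, 1.50
MASS_INTERCEPT, MASS_SLOPE = 13.33, 1.27

TRAITS = ("hfl", "mass", "fat")
SEASONS = ("late_winter", "summer", "early_winter")
AGE_CLASSES = ("newborn", "yearling", "adult")

# plausibility windows used to flag aberrant values (per trait; mass per class)
PLAUSIBILITY = {
    "hfl": (20.0, 70.0),
    "mass": {"newborn": (2.0, 15.0), "yearling": (20.0, 80.0),
             "adult": (40.0, 160.0)},
    "fat": (0.0, 30.0),
}


def metatarsus_to_hfl(meta_cm: float) -> float:
    """Hind foot length (cm) predicted from metatarsus length (cm)."""
    if not (10.0 < meta_cm < 60.0):
        raise ValueError(f"implausible metatarsus length: {meta_cm} cm")
    return HFL_INTERCEPT + HFL_SLOPE * meta_cm


def eviscerated_to_live(mass_evisc_kg: float, age_class: str,
                        age_offsets: dict | None = None) -> float:
    """Live mass (kg) predicted from eviscerated mass and age class.

    ``age_offsets`` maps age class to the additive Age term of the
    calibration; offsets default to 0 for every class.
    """
    if age_class not in AGE_CLASSES:
        raise ValueError(f"unknown age class: {age_class!r}")
    if mass_evisc_kg <= 0.1:
        raise ValueError("eviscerated mass must exceed 0.1 kg")
    offset = (age_offsets or {}).get(age_class, 0.0)
    return MASS_INTERCEPT + offset + MASS_SLOPE * mass_evisc_kg


def assign_age_class(age_months: float, trait: str) -> str | None:
    """Age class per the study cut-offs; None when excluded.

    Newborns are <= 1 month, yearlings 13-24 months, adults >= 25 months.
    For hind foot length the adult threshold is 2.5 years because leg
    bones keep growing until then: ages of 25-29 months are excluded
    from skeletal analyses rather than mislabelled.
    """
    if age_months < 0:
        raise ValueError("age cannot be negative")
    if age_months <= 1:
        return "newborn"
    if 13 <= age_months <= 24:
        return "yearling"
    if age_months >= 25:
        if trait == "hfl" and age_months < 30:
            return None  # not yet adult for skeletal analysis
        return "adult"
    return None  # 1-13 month gap: neither newborn nor yearling


def assign_season(date) -> str:
    """Season of a calendar date (month boundaries, see module docstring)."""
    month = pd.Timestamp(date).month
    if month <= 4:
        return "late_winter"
    if month <= 8:
        return "summer"
    return "early_winter"


def fit_date_polynomial(values, julian_days, max_order: int = 5):
    """Select a polynomial of Julian day by sequential nested F-tests.

    Orders 1..max_order are compared stepwise: order k+1 is preferred to
    order k only when the ANOVA F-test improves the fit at alpha = 0.05.
    Returns a ``numpy.polynomial.Polynomial`` (lowest order not
    significantly improved upon). Collinear or few distinct days cap the
    order.
    """
    values = np.asarray(values, dtype=float)
    days = np.asarray(julian_days, dtype=float)
    if values.size < max_order + 2:
        raise ValueError("need at least max_order + 2 points")
    distinct = np.unique(days).size
    cap = min(max_order, distinct - 1)
    if cap < 1:
        # all measurements on one day: nothing to standardize
        return np.polynomial.Polynomial([values.mean()])

    # fit on standardized days: raw day^5 spans ten orders of magnitude
    # and wrecks the conditioning of the nested F-tests
    m, s = days.mean(), days.std() or 1.0
    u = (days - m) / s

    def _fit(order):
        design = np.vander(u, N=order + 1, increasing=True)
        return sm.OLS(values, design).fit()

    order = 1
    current = _fit(order)
    while order < cap:
        nxt = _fit(order + 1)
        table = anova_lm(current, nxt)
        p = table["Pr(>F)"].iloc[1]
        if np.isnan(p) or p >= 0.05:
            break
        order += 1
        current = nxt
    # domain/window mapping evaluates the polynomial on raw days
    return np.polynomial.Polynomial(np.asarray(current.params),
                                    domain=[m - s, m + s],
                                    window=[-1.0, 1.0])


def standardize_to_mean_date(value: float, day: float, polynomial,
                             mean_day: float) -> float:
    """Adjust a trait value to the stratum's mean measurement day.

    Subtracts the fitted seasonal drift poly(day) − poly(mean_day); a
    value measured on the mean day is returned unchanged.
    """
    return value - (polynomial(day) - polynomial(mean_day))


@dataclass
class FilterReport:
    """Accounting of the ordered inclusion filters."""

    input_count: int = 0
    steps: list = field(default_factory=list)  # (name, removed, remaining)

    def log(self, name: str, removed: int, remaining: int):
        self.steps.append((name, int(removed), int(remaining)))

    @property
    def removed_total(self) -> int:
        return sum(r for _, r, _ in self.steps)

    @property
    def output_count(self) -> int:
        return self.steps[-1][2] if self.steps else self.input_count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["step", "removed", "remaining"])


def _plausible(df: pd.DataFrame) -> pd.Series:
    ok = np.ones(len(df), dtype=bool)
    value = df["value"].to_numpy(dtype=float)
    trait = df["trait"].to_numpy()
    cls = df["age_class"].to_numpy()
    for t, window in PLAUSIBILITY.items():
        mask = trait == t
        if not mask.any():
            continue
        if isinstance(window, dict):
            for c, (lo, hi) in window.items():
                m = mask & (cls == c)
                ok[m] &= (value[m] >= lo) & (value[m] <= hi)
        else:
            lo, hi = window
            ok[mask] &= (value[mask] >= lo) & (value[mask] <= hi)
    return pd.Series(ok, index=df.index)


def apply_inclusion_filters(obs: pd.DataFrame, *, seasonal: bool = False,
                            min_per_year: int = 5, min_years: int = 5,
                            min_per_season: int = 30
                            ) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the study's inclusion filters, in a fixed documented order.

    ``obs`` rows carry individual_id, herd, sex, age_class, trait, value,
    year (measurement year) and, for seasonal analyses, season. Steps:
    duplicates and aberrant values, herd switchers, male yearlings and
    adults, per-year n >= ``min_per_year`` (within trait x herd), trait x
    herd combinations with >= ``min_years`` years, and — seasonal
    analyses only — season x herd cells with >= ``min_per_season``
    individuals. Filtering is idempotent.
    """
    report = FilterReport(input_count=len(obs))
    if obs.empty:
        raise ValueError("no analyzable strata: empty input")
    df = obs.copy()

    n0 = len(df)
    df = df.drop_duplicates()
    df = df[_plausible(df)]
    report.log("duplicates_and_aberrant", n0 - len(df), len(df))

    herds_per_ind = df.groupby("individual_id")["herd"].nunique()
    switchers = set(herds_per_ind[herds_per_ind > 1].index)
    n0 = len(df)
    df = df[~df["individual_id"].isin(switchers)]
    report.log("herd_switchers", n0 - len(df), len(df))

    n0 = len(df)
    male_grown = (df["sex"] == "M") & df["age_class"].isin(["yearling", "adult"])
    df = df[~male_grown]
    report.log("male_yearlings_adults", n0 - len(df), len(df))

    n0 = len(df)
    counts = df.groupby(["trait", "herd", "year"])["value"].transform("size")
    df = df[counts >= min_per_year]
    report.log("years_below_min_n", n0 - len(df), len(df))

    n0 = len(df)
    nyears = df.groupby(["trait", "herd"])["year"].transform("nunique")
    df = df[nyears >= min_years]
    report.log("trait_herd_below_min_years", n0 - len(df), len(df))

    if seasonal:
        n0 = len(df)
        scounts = df.groupby(["trait", "herd", "season"])["value"].transform("size")
        df = df[scounts >= min_per_season]
        report.log("season_herd_below_min_n", n0 - len(df), len(df))

    if df.empty:
        raise ValueError("no analyzable strata after filtering")
    return df, report


def population_link_year(trait: str, age_class: str, cohort_year: int,
                         measurement_year: int) -> int:
    """Population year a trait observation should be regressed against.

    Skeletal size is fixed after early growth, so hind foot length links
    to the cohort year + 1 (the first full year of life) for yearlings
    and adults, and to the cohort year itself for newborns. Mass and fat
    reflect current conditions and link to the year of measurement.
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    if cohort_year > measurement_year:
        raise ValueError("cohort year cannot follow measurement year")
    if trait == "hfl":
        return cohort_year if age_class == "newborn" else cohort_year + 1
    return measurement_year


# ---------------------------------------------------------------------------
# record-level pipeline


def read_records_csv(path) -> pd.DataFrame:
    """Read the individual-measurement table, parsing dates."""
    return pd.read_csv(path, parse_dates=["date"])


def harmonize_records(records: pd.DataFrame, trait: str,
                      trajectory: PopulationTrajectory | None = None, *,
                      seasonal: bool = False, standardize_dates: bool = True,
                      age_offsets: dict | None = None,
                      min_per_year: int = 5, min_years: int = 5,
                      min_per_season: int = 30
                      ) -> tuple[pd.DataFrame, FilterReport]:
    """Full pipeline from raw records to linked trait observations.

    Conversions are applied first (metatarsus -> HFL when a direct HFL is
    absent, eviscerated -> live mass), then age class, season and link
    year are assigned, inclusion filters run, and values are standardized
    to the stratum mean date. Records whose link year falls outside the
    trajectory are dropped and counted. Newborn analyses keep June
    records only.
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    df = records.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    df["julian_day"] = df["date"].dt.dayofyear

    if trait == "hfl":
        value = df["hfl_cm"].astype(float)
        # converted values pool with direct measurements; keep provenance
        missing = value.isna() & df["metatarsus_cm"].notna()
        value[missing] = df.loc[missing, "metatarsus_cm"].map(metatarsus_to_hfl)
        df["source_measure"] = np.where(missing, "converted", "direct")
    elif trait == "mass":
        value = df["mass_live_kg"].astype(float)
        missing = value.isna() & df["mass_evisc_kg"].notna()
        df["source_measure"] = np.where(missing, "converted", "direct")
    else:
        value = df["fat_index"].astype(float)
        df["source_measure"] = "direct"
    df["value"] = value
    df["trait"] = trait

    df["age_class"] = [
        assign_age_class(a, trait) if pd.notna(a) else None
        for a in df["age_months"]
    ]
    if trait == "mass":
        evisc = df["value"].isna() & df["mass_evisc_kg"].notna()
        df.loc[evisc, "value"] = [
            eviscerated_to_live(m, c, age_offsets)
            for m, c in zip(df.loc[evisc, "mass_evisc_kg"],
                            df.loc[evisc, "age_class"])
        ]

    report = FilterReport(input_count=len(df))
    n0 = len(df)
    df = df[df["value"].notna() & df["age_class"].notna()]
    report.log("missing_trait_or_age", n0 - len(df), len(df))

    df["season"] = df["date"].map(assign_season)
    n0 = len(df)
    june_only = (df["age_class"] != "newborn") | (df["date"].dt.month == 6)
    df = df[june_only]
    report.log("newborns_outside_june", n0 - len(df), len(df))

    df, inner = apply_inclusion_filters(
        df, seasonal=seasonal, min_per_year=min_per_year,
        min_years=min_years, min_per_season=min_per_season)
    report.steps.extend(inner.steps)

    df["link_year"] = [
        population_link_year(trait, c, int(cy), int(y))
        for c, cy, y in zip(df["age_class"], df["cohort_year"], df["year"])
    ]
    if trajectory is not None:
        n0 = len(df)
        df = df[[ly in trajectory for ly in df["link_year"]]]
        report.log("link_year_outside_trajectory", n0 - len(df), len(df))
        if df.empty:
            raise ValueError("no analyzable strata: all link years outside "
                             "the trajectory")
        df["phase"] = [trajectory.phase_of(ly) for ly in df["link_year"]]

    if standardize_dates and len(df):
        strata = ["herd", "season"] if seasonal else ["herd"]
        adjusted = np.empty(len(df))
        df = df.reset_index(drop=True)
        for _, idx in df.groupby(strata).groups.items():
            sub = df.loc[idx]
            if len(sub) >= 7 and sub["julian_day"].nunique() >= 3:
                poly = fit_date_polynomial(sub["value"], sub["julian_day"])
                mean_day = float(sub["julian_day"].mean())
                adjusted[idx] = [
                    standardize_to_mean_date(v, d, poly, mean_day)
                    for v, d in zip(sub["value"], sub["julian_day"])
                ]
            else:
                adjusted[idx] = sub["value"]
        df["value"] = adjusted

    keep = ["individual_id", "herd", "sex", "age_class", "trait", "value",
            "year", "season", "link_year", "julian_day", "source_measure"]
    if "phase" in df:
        keep.append("phase")
    return df[keep].reset_index(drop=True), report
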