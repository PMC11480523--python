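import numpy as np
import pandas as pd
import pytest

from morphotrend import (GeneratingParams, McmcConfig, TrajectoryScenario,
                         build_trajectory, simulate_individuals,
                         simulate_trajectory)
from morphotrend.trajectory import SurveyEstimate


@pytest.fixture
def small_mcmc():
    """Desk-scale chain protocol for fast model tests."""
    return McmcConfig(chains=3, iterations=3_000, burn_in=1_000, thin=5,
                      seed=0)


@pytest.fixture
def growth_scenario():
    return TrajectoryScenario(
        years=(1990, 2001), shape="growth", start_size=100_000,
        end_size=250_000, survey_years=tuple(range(1990, 2002)),
        rel_error=0.0, missing_ci_fraction=0.0, herd="toy", seed=0)


@pytest.fixture
def noiseless_fit_inputs(growth_scenario):
    """Zero-noise surveys + zero-residual adult mass records."""
    true_sizes, surveys = simulate_trajectory(growth_scenario)
    trajectory = build_trajectory(surveys, span=0.75)
    params = GeneratingParams(alpha=80.0, beta=-0.5, sigma=0.0,
                              n_per_year=10, trait="mass",
                              age_class="adult", herd="toy",
                              repeat_fraction=0.0)
    records = simulate_individuals(true_sizes, params, seed=0)
    return true_sizes, trajectory, params, records


def make_surveys(years, estimates, half_widths, herd="toy"):
    out = []
    for y, e, h in zip(years, estimates, half_widths):
        out.append(SurveyEstimate(herd, int(y), float(e), float(e - h),
                                  float(e + h), 95, "field"))
    return out


@pytest.fixture
def toy_observations():
    """Hand-built observation table with known filter violations."""
    rows = []
    # 3 well-sampled years of adult females (kept)
    for year in (1990, 1991, 1992, 1993, 1994):
        for i in range(8):
            rows.append(dict(individual_id=f"f{year}{i}", herd="a", sex="F",
                             age_class="adult", trait="mass",
                             value=80.0 + i, year=year,
                             season="summer"))
    # a year with only 4 records (dropped by the n>=5 rule)
    for i in range(4):
        rows.append(dict(individual_id=f"s{i}", herd="a", sex="F",
                         age_class="adult", trait="mass", value=82.0,
                         year=1999, season="summer"))
    # adult males (dropped)
    for i in range(6):
        rows.append(dict(individual_id=f"m{i}", herd="a", sex="M",
                         age_class="adult", trait="mass", value=110.0,
                         year=1990, season="summer"))
    # a herd switcher (dropped)
    rows.append(dict(individual_id="switch", herd="a", sex="F",
                     age_class="adult", trait="mass", value=80.0,
                     year=1990, season="summer"))
    rows.append(dict(individual_id="switch", herd="b", sex="F",
                     age_class="adult", trait="mass", value=80.0,
                     year=1991, season="summer"))
    # an aberrant value (dropped)
    rows.append(dict(individual_id="fat1", herd="a", sex="F",
                     age_class="adult", trait="mass", value=500.0,
                     year=1990, season="summer"))
    # an exact duplicate (dropped)
    rows.append(dict(rows[0]))
    return pd.DataFrame(rows)
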