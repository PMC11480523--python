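"""Errors-in-variables model: density contract, sampler, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphotrend import (McmcConfig, ModelSpec, build_model, build_trajectory,
                         effect_translation, log_posterior, sample_posterior,
                         simulate_individuals, simulate_trajectory,
                         summarize_effects)
from morphotrend.eiv import PosteriorResult
from morphotrend.trajectory import PopulationTrajectory

from .conftest import make_surveys


def flat_trajectory(years, mean, sd):
    n = len(years)
    return PopulationTrajectory("toy", np.asarray(years),
                                np.full(n, mean), np.full(n, mean - sd),
                                np.full(n, mean + sd),
                                np.full(n, sd))


def obs_frame(values, link_years, age_class="adult", **extra):
    df = pd.DataFrame({"value": values, "link_year": link_years,
                       "age_class": age_class})
    for k, v in extra.items():
        df[k] = v
    return df


TOY_SPEC = ModelSpec(trait="mass", alpha_bounds=(0.0, 20.0), sigma_cap=10.0)


def test_log_posterior_matches_hand_computation():
    traj = flat_trajectory([2000], 20_000.0, 5_000.0)
    model = build_model(TOY_SPEC, obs_frame([10.0, 12.0], [2000, 2000]),
                        traj)
    point = {"alpha": [9.0], "beta": [0.5], "sigma": 1.0, "x": [2.2]}
    expected = (stats.norm.logpdf(10.0, 9.0 + 0.5 * 2.2, 1.0)
                + stats.norm.logpdf(12.0, 9.0 + 0.5 * 2.2, 1.0)
                + stats.norm.logpdf(2.2, 2.0, 0.5))
    assert log_posterior(point, model) == pytest.approx(expected)


@pytest.mark.parametrize("point", [
    {"alpha": [9.0], "beta": [1.5], "sigma": 1.0, "x": [2.0]},   # beta
    {"alpha": [30.0], "beta": [0.5], "sigma": 1.0, "x": [2.0]},  # alpha
    {"alpha": [9.0], "beta": [0.5], "sigma": 99.0, "x": [2.0]},  # sigma
    {"alpha": [9.0], "beta": [0.5], "sigma": 1.0, "x": [-1.0]},  # latent
])
def test_log_posterior_outside_support(point):
    traj = flat_trajectory([2000], 20_000.0, 5_000.0)
    model = build_model(TOY_SPEC, obs_frame([10.0, 12.0], [2000, 2000]),
                        traj)
    assert log_posterior(point, model) == -np.inf


def test_doubling_sigma_with_zero_residuals():
    """With exact fit, doubling sigma lowers the log posterior by N log 2."""
    traj = flat_trajectory([2000, 2001], 20_000.0, 5_000.0)
    # residuals are zero at alpha=10, beta=0, x anywhere
    model = build_model(TOY_SPEC, obs_frame([10.0] * 4,
                                            [2000, 2000, 2001, 2001]), traj)
    base = {"alpha": [10.0], "beta": [0.0], "sigma": 1.0, "x": [2.0, 2.0]}
    double = dict(base, sigma=2.0)
    assert (log_posterior(base, model) - log_posterior(double, model)
            == pytest.approx(4 * np.log(2)))


def test_parameter_counts_annual():
    traj = flat_trajectory(range(2000, 2006), 20_000.0, 5_000.0)
    obs = obs_frame([10.0] * 12, list(range(2000, 2006)) * 2)
    model = build_model(TOY_SPEC, obs, traj)
    # alpha, beta, sigma + one latent size per year
    assert model.n_params == 2 + 1 + 6


def test_phase_model_shares_alpha():
    years = list(range(2000, 2012))
    traj = flat_trajectory(years, 20_000.0, 5_000.0)
    phase = ["growth"] * 6 + ["decline"] * 6
    obs = obs_frame([10.0] * 12, years, phase=phase)
    spec = ModelSpec(trait="mass", phase_interaction=True,
                     alpha_bounds=(0, 20), sigma_cap=10)
    model = build_model(spec, obs, traj)
    assert model.alpha_labels == ["alpha"]
    assert model.beta_labels == ["beta[growth]", "beta[decline]"]


def test_phase_model_requires_five_years_each():
    years = list(range(2000, 2008))
    traj = flat_trajectory(years, 20_000.0, 5_000.0)
    obs = obs_frame([10.0] * 8, years,
                    phase=["growth"] * 2 + ["decline"] * 6)
    spec = ModelSpec(trait="mass", phase_interaction=True,
                     alpha_bounds=(0, 20), sigma_cap=10)
    with pytest.raises(ValueError, match="5 years in each phase"):
        build_model(spec, obs, traj)


def test_seasonal_model_shares_sigma():
    years = [2000, 2001] * 4
    traj = flat_trajectory([2000, 2001], 20_000.0, 5_000.0)
    obs = obs_frame([10.0] * 8, years,
                    season=["early_winter", "late_winter"] * 4)
    spec = ModelSpec(trait="fat", timescale="seasonal",
                     seasons=("early_winter", "late_winter"),
                     alpha_bounds=(0, 30), sigma_cap=10)
    model = build_model(spec, obs, traj)
    assert model.alpha_labels == ["alpha[early_winter]",
                                  "alpha[late_winter]"]
    assert model.n_params == 2 + 2 + 1 + 2


def _wls_oracle_dataset():
    rng = np.random.default_rng(11)
    years = np.arange(1990, 2000)
    x = np.linspace(5, 15, 10)          # scaled sizes, known exactly
    n_per = 20
    values, links = [], []
    for y, xi in zip(years, x):
        values += list(10.0 + 0.4 * xi + rng.normal(0, 1.0, n_per))
        links += [y] * n_per
    traj = PopulationTrajectory("toy", years, x * 1e4, x * 1e4, x * 1e4,
                                np.zeros(10))
    return obs_frame(values, links), traj, x


def test_clamped_latents_match_least_squares(small_mcmc):
    """With latent sizes clamped, the posterior mean of beta equals the
    ordinary least-squares slope (conjugate flat-prior case)."""
    obs, traj, x = _wls_oracle_dataset()
    spec = ModelSpec(trait="mass", alpha_bounds=(0, 40), sigma_cap=10)
    model = build_model(spec, obs, traj)
    res = sample_posterior(model, small_mcmc)
    xs = np.repeat(x, 20)
    slope = np.polyfit(xs, obs["value"], 1)[0]
    beta = res.draws["beta"].reshape(-1)
    mc_se = beta.std() / np.sqrt(res.summary.loc["beta", "n_eff"])
    assert beta.mean() == pytest.approx(slope, abs=max(3 * mc_se, 5e-3))


def test_attenuation_direction(small_mcmc):
    """Acknowledging size uncertainty never tightens the slope posterior."""
    obs, traj, x = _wls_oracle_dataset()
    wide = PopulationTrajectory("toy", traj.years, traj.mean,
                                traj.mean - 2e4, traj.mean + 2e4,
                                np.full(10, 1e4))
    spec = ModelSpec(trait="mass", alpha_bounds=(0, 40), sigma_cap=10)
    free = sample_posterior(build_model(spec, obs, wide), small_mcmc)
    clamped = sample_posterior(build_model(spec, obs, wide).clamped(),
                               small_mcmc)
    sd_free = free.draws["beta"].std()
    sd_clamped = clamped.draws["beta"].std()
    assert sd_clamped <= sd_free * 1.15


def test_zero_noise_concentrates_on_generating_slope(noiseless_fit_inputs,
                                                     small_mcmc):
    from morphotrend import harmonize_records
    _, traj, params, records = noiseless_fit_inputs
    obs, _ = harmonize_records(records, "mass", traj,
                               standardize_dates=False)
    spec = ModelSpec(trait="mass")
    res = sample_posterior(build_model(spec, obs, traj), small_mcmc)
    s = res.summary.loc["beta"]
    assert s["estimate"] == pytest.approx(params.beta, abs=0.02)
    assert s["uci"] - s["lci"] < 0.02


def test_draw_counts_and_prior_containment(small_mcmc):
    obs, traj, _ = _wls_oracle_dataset()
    spec = ModelSpec(trait="mass", alpha_bounds=(0, 40), sigma_cap=10)
    res = sample_posterior(build_model(spec, obs, traj), small_mcmc)
    assert res.retained_total() == small_mcmc.retained_total == 1200
    beta = res.draws["beta"]
    alpha = res.draws["alpha"]
    assert np.all((beta >= -1) & (beta <= 1))
    assert np.all((alpha >= 0) & (alpha <= 40))
    assert np.all(res.draws["sigma"] > 0)
    for name in res.draws:
        if name.startswith("popsize"):
            assert np.all(res.draws[name] >= 0)


def test_full_protocol_retains_12000_draws():
    assert McmcConfig().retained_total == 12_000


def test_sampler_determinism(small_mcmc):
    obs, traj, _ = _wls_oracle_dataset()
    spec = ModelSpec(trait="mass", alpha_bounds=(0, 40), sigma_cap=10)
    model = build_model(spec, obs, traj)
    a = sample_posterior(model, small_mcmc)
    b = sample_posterior(model, small_mcmc)
    for name in a.draws:
        np.testing.assert_array_equal(a.draws[name], b.draws[name])


def test_summarize_effects_significance():
    rng = np.random.default_rng(0)
    draws = {"beta[growth]": rng.normal(0.5, 0.05, (2, 500)),
             "beta[decline]": rng.normal(0.0, 0.2, (2, 500))}
    res = PosteriorResult(model=None, config=None, draws=draws)
    eff = summarize_effects(res)
    assert bool(eff.loc["beta[growth]", "significant"]) is True
    assert bool(eff.loc["beta[decline]", "significant"]) is False
    flat = np.sort(draws["beta[growth]"].reshape(-1))
    assert eff.loc["beta[growth]", "lci"] == pytest.approx(
        np.quantile(flat, 0.025), abs=1e-9)


@pytest.mark.parametrize("beta, delta, expected", [
    (0.61, 50_000, 3.05),     # ~3 kg per 50,000 caribou
    (-0.03, 300_000, -0.9),   # -0.9 cm per 300,000 caribou
    (0.0, 123_456, 0.0),
])
def test_effect_translation(beta, delta, expected):
    assert effect_translation(beta, delta) == pytest.approx(expected)


def test_effect_translation_rejects_nonfinite():
    with pytest.raises(ValueError):
        effect_translation(np.nan, 1000)
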