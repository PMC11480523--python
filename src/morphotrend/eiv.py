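"""Bayesian errors-in-variables regression of a trait on latent herd size.

The scientific question is whether a morphological trait (hind foot
length, body mass, body-fat index) tracks population size. Population
size is itself only known up to survey uncertainty, so it enters the
regression as a latent variable with an informative annual prior taken
from the smoothed survey trajectory:

    trait_i      ~ Normal(mu_year(i), sigma)
    mu_year      = alpha + beta * popsize_year            (annual)
    mu_year      = alpha + beta_phase * popsize_year      (phase-varying)
    mu_year      = alpha_season + beta_season * popsize_year  (seasonal)
    popsize_year ~ Normal(traj_mean_year, traj_sd_year), truncated >= 0

Population size is expressed in units of 10,000 individuals, so beta is
"trait units per 10,000 caribou". Priors: beta ~ Uniform(-1, 1) per
phase/season, alpha ~ Uniform over the trait's plausibility window,
sigma ~ Uniform(0, trait-specific cap). A single residual sd sigma is
shared across seasons and phases within a model.

Every full conditional is available in closed form (truncated Normals
for alpha, beta and the latent sizes; a truncated inverse-gamma for
sigma^2), so the sampler is a plain Gibbs scheme — exact, seeded and
fast-mixing. ``log_posterior`` exposes the target density as the
testable contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .diagnostics import effective_n, gelman_rubin
from .harmonize import PLAUSIBILITY
from .trajectory import PopulationTrajectory

__all__ = [
    "POP_SCALE", "SIGMA_CAPS", "ModelSpec", "McmcConfig", "EivModel",
    "PosteriorResult", "build_model", "log_posterior", "sample_posterior",
    "summarize_effects", "effect_translation",
]

POP_SCALE = 10_000.0  # population size enters the regression per 10,000 head

SIGMA_CAPS = {"hfl": 10.0, "mass": 30.0, "fat": 10.0}

BETA_LO, BETA_HI = -1.0, 1.0


def default_alpha_bounds(trait: str, age_class: str) -> tuple[float, float]:
    window = PLAUSIBILITY[trait]
    return window[age_class] if isinstance(window, dict) else window


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what, and over which strata."""

    trait: str
    herd: str = ""
    age_class: str = "adult"
    timescale: str = "annual"  # "annual" or "seasonal"
    phase_interaction: bool = False
    seasons: tuple = ()
    alpha_bounds: tuple | None = None
    sigma_cap: float | None = None
    scale: float = POP_SCALE

    def __post_init__(self):
        if self.timescale not in ("annual", "seasonal"):
            raise ValueError("timescale must be 'annual' or 'seasonal'")
        if self.phase_interaction and self.timescale == "seasonal":
            raise ValueError("phase and season interactions are separate models")

    def resolved_alpha_bounds(self) -> tuple[float, float]:
        return self.alpha_bounds or default_alpha_bounds(self.trait,
                                                         self.age_class)

    def resolved_sigma_cap(self) -> float:
        return self.sigma_cap or SIGMA_CAPS[self.trait]


@dataclass(frozen=True)
class McmcConfig:
    """Chain protocol. Defaults follow the full study protocol."""

    chains: int = 3
    iterations: int = 100_000
    burn_in: int = 60_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be below iterations")
        if (self.iterations - self.burn_in) % self.thin:
            raise ValueError("(iterations - burn_in) must divide by thin")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    @property
    def retained_total(self) -> int:
        return self.chains * self.retained_per_chain

    @classmethod
    def reduced(cls, seed: int = 0) -> "McmcConfig":
        """Desk-scale protocol for recovery experiments."""
        return cls(chains=3, iterations=10_000, burn_in=5_000, thin=5,
                   seed=seed)


@dataclass
class EivModel:
    """Assembled data + priors, ready for the sampler."""

    spec: ModelSpec
    t: np.ndarray                  # trait values, length N
    alpha_idx: np.ndarray          # obs -> intercept group
    beta_idx: np.ndarray           # obs -> slope group
    year_idx: np.ndarray           # obs -> latent year
    alpha_labels: list
    beta_labels: list
    years: np.ndarray              # distinct link years
    x_mean: np.ndarray             # latent prior means (scaled)
    x_sd: np.ndarray               # latent prior sds (scaled)
    alpha_bounds: tuple
    sigma_cap: float

    @property
    def n_obs(self) -> int:
        return self.t.size

    @property
    def n_params(self) -> int:
        """alphas + betas + sigma + one latent size per year."""
        return len(self.alpha_labels) + len(self.beta_labels) + 1 + self.years.size

    def clamped(self) -> "EivModel":
        """Copy with latent sizes clamped at their prior means (no Eq.-5
        uncertainty); used to quantify what the errors-in-variables layer
        contributes."""
        return replace(self, x_sd=np.zeros_like(self.x_sd))


def build_model(spec: ModelSpec, observations: pd.DataFrame,
                trajectory: PopulationTrajectory,
                min_years_per_phase: int = 5) -> EivModel:
    """Assemble the model for one herd x trait x age-class stratum.

    ``observations`` must carry columns value and link_year, plus phase
    (for phase interactions) or season (for seasonal models). Phase
    interactions require at least ``min_years_per_phase`` distinct years
    of data in each phase.
    """
    obs = observations
    if spec.age_class and "age_class" in obs:
        obs = obs[obs["age_class"] == spec.age_class]
    if obs.empty:
        raise ValueError("no observations for this stratum")
    missing = [ly for ly in obs["link_year"].unique() if ly not in trajectory]
    if missing:
        raise ValueError(f"link years outside trajectory: {sorted(missing)}")

    t = obs["value"].to_numpy(dtype=float)
    years = np.sort(obs["link_year"].unique()).astype(int)
    year_pos = {y: i for i, y in enumerate(years)}
    year_idx = obs["link_year"].map(year_pos).to_numpy(dtype=int)

    if spec.timescale == "seasonal":
        seasons = list(spec.seasons) or sorted(obs["season"].unique())
        obs_season = obs["season"].to_numpy()
        keep = np.isin(obs_season, seasons)
        if not keep.all():
            raise ValueError("observations outside the requested seasons")
        alpha_labels = [f"alpha[{s}]" for s in seasons]
        beta_labels = [f"beta[{s}]" for s in seasons]
        pos = {s: i for i, s in enumerate(seasons)}
        alpha_idx = np.array([pos[s] for s in obs_season])
        beta_idx = alpha_idx.copy()
    elif spec.phase_interaction:
        phases = obs["phase"].to_numpy()
        for phase in ("growth", "decline"):
            n_years = obs.loc[phases == phase, "link_year"].nunique()
            if n_years < min_years_per_phase:
                raise ValueError(
                    f"phase interaction requires at least "
                    f"{min_years_per_phase} years in each phase; "
                    f"{phase!r} has {n_years}")
        labels = ["growth", "decline"]
        pos = {p: i for i, p in enumerate(labels)}
        alpha_labels = ["alpha"]
        beta_labels = [f"beta[{p}]" for p in labels]
        alpha_idx = np.zeros(len(obs), dtype=int)
        beta_idx = np.array([pos[p] for p in phases])
    else:
        alpha_labels, beta_labels = ["alpha"], ["beta"]
        alpha_idx = np.zeros(len(obs), dtype=int)
        beta_idx = np.zeros(len(obs), dtype=int)

    prior = np.array([trajectory.prior_for(y) for y in years], dtype=float)
    return EivModel(
        spec=spec, t=t, alpha_idx=alpha_idx, beta_idx=beta_idx,
        year_idx=year_idx, alpha_labels=alpha_labels,
        beta_labels=beta_labels, years=years,
        x_mean=prior[:, 0] / spec.scale, x_sd=prior[:, 1] / spec.scale,
        alpha_bounds=spec.resolved_alpha_bounds(),
        sigma_cap=spec.resolved_sigma_cap())


# ---------------------------------------------------------------------------
# target density


def _normal_logpdf(x, mean, sd):
    return -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def log_posterior(point: dict, model: EivModel) -> float:
    """Log posterior density at ``point`` (up to the uniform-prior constant).

    ``point`` maps "alpha" and "beta" to arrays over their groups,
    "sigma" to a scalar and "x" to the scaled latent sizes. Returns -inf
    outside the prior support.
    """
    alpha = np.atleast_1d(np.asarray(point["alpha"], dtype=float))
    beta = np.atleast_1d(np.asarray(point["beta"], dtype=float))
    sigma = float(point["sigma"])
    x = np.atleast_1d(np.asarray(point["x"], dtype=float))
    if not (np.all(np.isfinite(alpha)) and np.all(np.isfinite(beta))
            and np.isfinite(sigma) and np.all(np.isfinite(x))):
        raise ValueError("non-finite parameter point")
    lo, hi = model.alpha_bounds
    if (np.any(beta < BETA_LO) or np.any(beta > BETA_HI)
            or np.any(alpha < lo) or np.any(alpha > hi)
            or not (0.0 < sigma < model.sigma_cap) or np.any(x < 0)):
        return -np.inf
    mu = alpha[model.alpha_idx] + beta[model.beta_idx] * x[model.year_idx]
    lp = _normal_logpdf(model.t, mu, sigma).sum()
    free = model.x_sd > 0
    lp += _normal_logpdf(x[free], model.x_mean[free], model.x_sd[free]).sum()
    if np.any(x[~free] != model.x_mean[~free]):
        return -np.inf  # clamped latent sizes are fixed at their means
    return float(lp)


# ---------------------------------------------------------------------------
# Gibbs sampler


def _trunc_normal(rng, mean, sd, lo, hi):
    """Vectorized truncated-Normal draw by inverse-CDF."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    out = np.clip(mean, lo, hi)
    ok = np.broadcast_to(sd > 0, out.shape)
    if not np.any(ok):
        return out
    a = ndtr((lo - mean) / np.where(sd > 0, sd, 1.0))
    b = ndtr((hi - mean) / np.where(sd > 0, sd, 1.0))
    u = rng.random(out.shape)
    p = np.clip(a + u * (b - a), 1e-15, 1.0 - 1e-15)
    draw = mean + sd * ndtri(p)
    return np.where(ok, np.clip(draw, lo, hi), out)


def _run_chain(model: EivModel, config: McmcConfig, rng: np.random.Generator):
    t, a_idx, b_idx, y_idx = model.t, model.alpha_idx, model.beta_idx, model.year_idx
    n_a, n_b = len(model.alpha_labels), len(model.beta_labels)
    n_y, N = model.years.size, t.size
    lo_a, hi_a = model.alpha_bounds
    cap = model.sigma_cap
    sd_safe = np.where(model.x_sd > 0, model.x_sd, 1.0)
    prior_prec = np.where(model.x_sd > 0, 1.0 / sd_safe ** 2, 0.0)
    fixed_x = model.x_sd == 0
    counts_a = np.bincount(a_idx, minlength=n_a).astype(float)

    # over-dispersed but in-support starting point
    x = np.clip(model.x_mean * np.exp(rng.normal(0, 0.05, n_y)), 0.0, None)
    alpha = np.clip(
        np.bincount(a_idx, weights=t, minlength=n_a) / np.maximum(counts_a, 1)
        + rng.normal(0, 1.0, n_a), lo_a, hi_a)
    beta = np.clip(rng.normal(0, 0.1, n_b), BETA_LO, BETA_HI)
    sigma = float(np.clip(t.std() + rng.normal(0, 0.1), 1e-3, cap * 0.99))

    keep = config.retained_per_chain
    out = {"alpha": np.empty((keep, n_a)), "beta": np.empty((keep, n_b)),
           "sigma": np.empty(keep), "x": np.empty((keep, n_y))}
    k = 0
    ones = np.ones(N)
    design = np.zeros((N, n_a + n_b))
    obs_rows = np.arange(N)

    def _coef_block(alpha, beta, sigma, x):
        """Joint (alpha, beta) draw from the multivariate-Normal full
        conditional; alpha and beta are near-collinear when x is far from
        zero, so a blocked draw is essential for mixing. Falls back to
        coordinatewise truncated updates if the box prior keeps rejecting."""
        z = x[y_idx]
        design[:, :] = 0.0
        design[obs_rows, a_idx] = 1.0
        design[obs_rows, n_a + b_idx] = z
        xtx = design.T @ design
        xty = design.T @ t
        # ridge on empty groups so the solve stays defined
        empty = np.diag(xtx) == 0
        if empty.any():
            xtx[empty, empty] = 1.0
        try:
            chol = np.linalg.cholesky(xtx)
        except np.linalg.LinAlgError:
            chol = np.linalg.cholesky(xtx + 1e-9 * np.eye(n_a + n_b))
        mean = np.linalg.solve(xtx, xty)
        for _ in range(50):
            draw = mean + sigma * np.linalg.solve(
                chol.T, rng.standard_normal(n_a + n_b))
            a_draw, b_draw = draw[:n_a], draw[n_a:]
            if (np.all((a_draw >= lo_a) & (a_draw <= hi_a))
                    and np.all(np.abs(b_draw) <= BETA_HI)):
                return a_draw, b_draw
        # coordinatewise truncated fallback (rare: posterior pinned to box)
        s2 = sigma * sigma
        resid_a = np.bincount(a_idx, weights=t - beta[b_idx] * z,
                              minlength=n_a)
        alpha = _trunc_normal(rng, resid_a / counts_a,
                              sigma / np.sqrt(counts_a), lo_a, hi_a)
        res = t - alpha[a_idx]
        den = np.bincount(b_idx, weights=z * z, minlength=n_b)
        num = np.bincount(b_idx, weights=z * res, minlength=n_b)
        safe = den > 0
        b_mean = np.where(safe, num / np.maximum(den, 1e-300), 0.0)
        b_sd = np.where(safe, sigma / np.sqrt(np.maximum(den, 1e-300)), 0.0)
        beta = _trunc_normal(rng, b_mean, b_sd, BETA_LO, BETA_HI)
        beta[~safe] = rng.uniform(BETA_LO, BETA_HI, (~safe).sum())
        return alpha, beta

    for it in range(config.iterations):
        s2 = sigma * sigma
        alpha, beta = _coef_block(alpha, beta, sigma, x)
        res = t - alpha[a_idx]
        # latent sizes | rest: conjugate Normal per year, truncated at 0
        b_obs = beta[b_idx]
        A = prior_prec + np.bincount(y_idx, weights=b_obs * b_obs,
                                     minlength=n_y) / s2
        B = prior_prec * model.x_mean + np.bincount(
            y_idx, weights=b_obs * res, minlength=n_y) / s2
        pos = A > 0
        x_mean = np.where(pos, B / np.maximum(A, 1e-300), model.x_mean)
        x_sd = np.where(pos, 1.0 / np.sqrt(np.maximum(A, 1e-300)), 0.0)
        x = _trunc_normal(rng, x_mean, x_sd, 0.0, np.inf)
        x[fixed_x] = model.x_mean[fixed_x]
        # sigma^2 | rest: inverse-gamma truncated to (0, cap^2)
        mu = alpha[a_idx] + beta[b_idx] * x[y_idx]
        ss = float(np.sum((t - mu) ** 2))
        shape = (N - 1) / 2.0
        for _ in range(100):
            v = ss / 2.0 / rng.gamma(shape)
            if v < cap * cap:
                break
        else:
            v = (cap * (1.0 - 1e-9 * rng.random())) ** 2
        sigma = float(np.sqrt(max(v, 1e-300)))

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            out["alpha"][k] = alpha
            out["beta"][k] = beta
            out["sigma"][k] = sigma
            out["x"][k] = x
            k += 1
    return out


@dataclass
class PosteriorResult:
    """Retained draws, summaries and diagnostics for one fitted model."""

    model: EivModel
    config: McmcConfig
    draws: dict                      # name -> (chains, draws) array
    summary: pd.DataFrame = field(default=None)
    converged: bool = field(default=None)

    def __post_init__(self):
        if self.summary is None:
            rows = []
            for name, arr in self.draws.items():
                flat = arr.reshape(-1)
                rows.append({
                    "parameter": name,
                    "estimate": float(flat.mean()),
                    "lci": float(np.quantile(flat, 0.025)),
                    "uci": float(np.quantile(flat, 0.975)),
                    "rhat": gelman_rubin(arr),
                    "n_eff": effective_n(arr),
                })
            self.summary = pd.DataFrame(rows).set_index("parameter")
            self.converged = bool((self.summary["rhat"] < 1.1).all())

    @property
    def beta_names(self) -> list:
        return [n for n in self.draws if n.startswith("beta")]

    def beta_summary(self, level: float = 0.95) -> pd.DataFrame:
        return summarize_effects(self, level=level)

    def retained_total(self) -> int:
        first = next(iter(self.draws.values()))
        return int(first.shape[0] * first.shape[1])


def sample_posterior(model: EivModel, config: McmcConfig) -> PosteriorResult:
    """Run the Gibbs sampler; reproducible given ``config.seed``."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains = [_run_chain(model, config, np.random.default_rng(s))
              for s in seeds]
    draws = {}
    for j, label in enumerate(model.alpha_labels):
        draws[label] = np.stack([c["alpha"][:, j] for c in chains])
    for j, label in enumerate(model.beta_labels):
        draws[label] = np.stack([c["beta"][:, j] for c in chains])
    draws["sigma"] = np.stack([c["sigma"] for c in chains])
    for j, year in enumerate(model.years):
        draws[f"popsize[{year}]"] = np.stack(
            [c["x"][:, j] for c in chains]) * model.spec.scale
    return PosteriorResult(model=model, config=config, draws=draws)


def summarize_effects(result: PosteriorResult,
                      level: float = 0.95) -> pd.DataFrame:
    """Per-slope posterior mean, equal-tailed CI and significance call.

    An effect is called significant when its credible interval excludes
    zero.
    """
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for name in result.beta_names:
        flat = result.draws[name].reshape(-1)
        lci, uci = np.quantile(flat, [lo_q, hi_q])
        rows.append({"parameter": name, "estimate": float(flat.mean()),
                     "lci": float(lci), "uci": float(uci),
                     "significant": bool(lci > 0 or uci < 0)})
    return pd.DataFrame(rows).set_index("parameter")


def effect_translation(beta: float, delta_pop_individuals: float) -> float:
    """Trait change implied by a change in head count.

    beta is per 10,000 individuals, so e.g. beta = 0.61 over 50,000
    additional caribou translates to 0.61 * 5 = 3.05 trait units.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return beta * delta_pop_individuals / POP_SCALE
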