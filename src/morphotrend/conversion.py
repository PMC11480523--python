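"""Calibration of measurement conversions by mixed-model selection.

Two conversions harmonize the morphometric record: metatarsus length to
hind foot length, and eviscerated to live mass. Each is a linear mixed
regression with a year random intercept, fitted by maximum likelihood
over a small candidate set of fixed-effect structures (null, +sex, +age,
+sex+age, +sex x age). Candidates are ranked by AICc and the retained
model follows the Arnold rule: among candidates within dAICc < 2 of the
best, prefer the one with the fewest fixed parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

__all__ = ["ConversionModel", "CANDIDATES", "aicc", "select_by_aicc",
           "fit_conversion_model"]

# candidate fixed-effect structures, all with a year random intercept
CANDIDATES = {
    "null": "y ~ x",
    "+sex": "y ~ x + sex",
    "+age": "y ~ x + age_class",
    "+sex+age": "y ~ x + sex + age_class",
    "+sex:age": "y ~ x + sex * age_class",
}


def aicc(llf: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: AIC + 2k(k+1)/(n−k−1)."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def select_by_aicc(table: pd.DataFrame, delta: float = 2.0) -> str:
    """Arnold rule on an AICc table with columns [name, aicc, k_fixed].

    The lowest-AICc candidate is retained unless another candidate within
    ``delta`` of it has fewer fixed parameters, in which case the
    fewest-parameter such candidate (ties broken by AICc) is retained.
    """
    t = table[np.isfinite(table["aicc"])]
    if t.empty:
        raise ValueError("no candidate with a finite AICc")
    t = t.sort_values("aicc").reset_index(drop=True)
    close = t[t["aicc"] - t["aicc"].iloc[0] < delta]
    winner = close.sort_values(["k_fixed", "aicc"]).iloc[0]
    return str(winner["name"])


@dataclass
class ConversionModel:
    """A retained calibration: fixed coefficients + year random variance."""

    kind: str  # "metatarsus->hfl" or "eviscerated->live"
    retained: str
    coefficients: dict
    slope: float
    year_variance: float
    aicc_table: pd.DataFrame
    normality_p: float = field(default=np.nan)

    def predict(self, x: float, **covariates) -> float:
        """Point prediction with the year random effect at its zero mean."""
        val = self.coefficients.get("Intercept", 0.0) + self.slope * x
        for name, coef in self.coefficients.items():
            for cov, level in covariates.items():
                if name == f"{cov}[T.{level}]":
                    val += coef
        return val


def fit_conversion_model(pairs: pd.DataFrame, candidates=None,
                         kind: str = "metatarsus->hfl") -> ConversionModel:
    """Fit and select the conversion mixed model.

    ``pairs`` must carry columns x, y, year and (when the corresponding
    candidates are requested) sex and age_class. Models are fitted by ML
    so that AICc comparisons across fixed structures are valid. A
    candidate whose fit fails or is singular is dropped with a warning.
    """
    if len(pairs) < 10:
        raise ValueError("insufficient calibration pairs (need >= 10)")
    if candidates is None:
        candidates = list(CANDIDATES)
    unknown = set(candidates) - set(CANDIDATES)
    if unknown:
        raise ValueError(f"unknown candidates: {sorted(unknown)}")

    rows, fits = [], {}
    n = len(pairs)
    for name in candidates:
        formula = CANDIDATES[name]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, pairs, groups=pairs["year"])
                fit = model.fit(reml=False, method="bfgs")
                if not np.isfinite(fit.llf):
                    fit = model.fit(reml=False, method="powell")
            if not (np.all(np.isfinite(fit.params))
                    and np.isfinite(fit.llf)):
                raise ValueError("non-finite estimates")
        except Exception as exc:  # singular / failed candidate
            warnings.warn(f"candidate {name!r} dropped: {exc}")
            continue
        k_fixed = len(fit.fe_params)
        k = k_fixed + 2  # + year random variance + residual variance
        rows.append({"name": name, "aicc": aicc(fit.llf, k, n),
                     "k_fixed": k_fixed, "k": k, "loglik": fit.llf})
        fits[name] = fit
    if not rows:
        raise ValueError("all candidate models failed")

    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    retained = select_by_aicc(table)
    fit = fits[retained]
    resid = np.asarray(fit.resid, dtype=float)
    # Shapiro on a subsample: the diagnostic, not a gatekeeper
    sample = resid if resid.size <= 5000 else resid[:5000]
    normality_p = float(scipy.stats.shapiro(sample).pvalue)
    coefficients = dict(fit.fe_params)
    return ConversionModel(
        kind=kind, retained=retained, coefficients=coefficients,
        slope=float(coefficients["x"]),
        year_variance=float(fit.cov_re.iloc[0, 0]),
        aicc_table=table, normality_p=normality_p)
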