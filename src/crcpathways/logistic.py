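"""Binary logistic regression by IRLS, with the four cohort model specs.

The cohort analysis fits four models with reference categories fixed at
left side / late stage / symptomatic pathway / male sex:

* A: right-sided ~ pathway + sex (multivariable)
* B: right-sided ~ Hb (g/l)
* C: right-sided ~ age (years)
* D: early-stage ~ pathway

The fitter is written from first principles (Newton-Raphson / iteratively
reweighted least squares on the Bernoulli log-likelihood) with Wald
standard errors from the inverse observed information; odds ratios carry
95% Wald intervals and two-sided Wald p-values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .cohort import Cohort, PATHWAYS

Z_975 = 1.959963984540054
SEPARATION_BOUND = 15.0  # |logit-scale coefficient| beyond this flags separation


class FitError(ValueError):
    pass


class SeparationError(FitError):
    pass


MODEL_SPECS: dict[str, dict] = {
    "A": {"outcome": "side_right", "predictors": ["pathway", "sex"]},
    "B": {"outcome": "side_right", "predictors": ["hb"]},
    "C": {"outcome": "side_right", "predictors": ["age"]},
    "D": {"outcome": "stage_early", "predictors": ["pathway"]},
}


@dataclass(frozen=True)
class LogisticFit:
    names: tuple[str, ...]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        return np.exp(self.coef - Z_975 * self.se), np.exp(self.coef + Z_975 * self.se)

    @property
    def p_values(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))


def _bernoulli_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    # log L = sum y*eta - log(1 + e^eta), stable via logaddexp
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: Optional[Sequence[str]] = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by Newton-Raphson (IRLS).

    ``X`` must include the intercept column.  Convergence is declared when
    the log-likelihood improves by less than ``tol``.  Raises on constant
    outcomes, rank-deficient designs and (quasi-)complete separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise FitError("design rows must match outcome length")
    if y.min() == y.max():
        raise FitError("outcome is constant; logistic model is not identifiable")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("design matrix is rank deficient")
    names = tuple(names) if names is not None else tuple(f"x{j}" for j in range(X.shape[1]))

    beta = np.zeros(X.shape[1])
    ll = _bernoulli_loglik(beta, X, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = special.expit(eta)
        w = p * (1.0 - p)
        # Newton step: (X' W X)^-1 X' (y - p)
        XtW = X.T * w
        info = XtW @ X
        grad = X.T @ (y - p)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise FitError("observed information is singular") from None
        new_beta = beta + step
        new_ll = _bernoulli_loglik(new_beta, X, y)
        # step-halving if the full Newton step overshoots
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll = _bernoulli_loglik(new_beta, X, y)
            halvings += 1
        beta = new_beta
        if np.any(np.abs(beta) > SEPARATION_BOUND):
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"apparent separation: coefficient for {names[j]!r} exceeded "
                f"{SEPARATION_BOUND} on the logit scale"
            )
        if new_ll - ll < tol and it > 1:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    eta = X @ beta
    p = special.expit(eta)
    w = p * (1.0 - p)
    info = (X.T * w) @ X
    cov = np.linalg.inv(info)
    return LogisticFit(
        names=names,
        coef=beta,
        cov=cov,
        loglik=ll,
        converged=converged,
        n_iter=it,
        n_obs=len(y),
    )


# ---------------------------------------------------------------------------
# Cohort model specs
# ---------------------------------------------------------------------------

def _design_from_cohort(cohort: Cohort, spec: dict):
    df = cohort.to_dataframe()
    for p in ("IDA", "BCSP"):
        if spec["predictors"] == ["pathway"] or "pathway" in spec["predictors"]:
            if (df["pathway"] == p).sum() == 0:
                raise FitError(f"pathway {p} absent from cohort")
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for pred in spec["predictors"]:
        if pred == "pathway":
            cols.append((df["pathway"] == "IDA").to_numpy(float))
            names.append("pathway_IDA")
            cols.append((df["pathway"] == "BCSP").to_numpy(float))
            names.append("pathway_BCSP")
        elif pred == "sex":
            cols.append((df["sex"] == "F").to_numpy(float))
            names.append("sex_female")
        elif pred == "hb":
            cols.append(df["hb_g_l"].to_numpy(float))
            names.append("hb_g_l")
        elif pred == "age":
            cols.append(df["age"].to_numpy(float))
            names.append("age_years")
        else:  # pragma: no cover
            raise FitError(f"unknown predictor {pred!r}")
    X = np.column_stack(cols)
    if spec["outcome"] == "side_right":
        y = (df["side"] == "right").to_numpy(float)
    else:
        y = (df["stage_category"] == "early").to_numpy(float)
    return X, y, names


def fit_reference_models(cohort: Cohort) -> dict[str, LogisticFit]:
    """Fit the four named model specifications A-D on a cohort."""
    out = {}
    for label, spec in MODEL_SPECS.items():
        X, y, names = _design_from_cohort(cohort, spec)
        out[label] = fit_logistic(X, y, names=names)
    return out


def hb_effect_simulation(
    n: int,
    true_or_per_g_l: float,
    seed: int = 0,
    hb_mixture=None,
) -> LogisticFit:
    """Simulate (Hb, side) pairs at a known per-g/l odds ratio and fit
    side ~ Hb.

    Hb is drawn from the pooled cohort mixture by default; the intercept is
    solved so the marginal right-sided proportion matches the cohort margin.
    """
    from .synthetic import pooled_hb_mixture, solve_hb_intercept

    if n <= 0:
        raise FitError(f"n must be positive, got {n}")
    if not true_or_per_g_l > 0:
        raise FitError("true_or_per_g_l must be positive")
    mix = hb_mixture if hb_mixture is not None else pooled_hb_mixture()
    alpha = solve_hb_intercept(true_or_per_g_l)
    rng = np.random.default_rng(seed)
    hb = mix.sample(rng, n)
    p = special.expit(alpha + math.log(true_or_per_g_l) * hb)
    y = (rng.random(n) < p).astype(float)
    X = np.column_stack([np.ones(n), hb])
    return fit_logistic(X, y, names=("intercept", "hb_g_l"))


def format_p(p: float) -> str:
    return "< 0.0001" if p < 1e-4 else f"{p:.4g}"


def wald_or_table(fit: LogisticFit, include_intercept: bool = False) -> pd.DataFrame:
    """Odds ratios with 95% Wald intervals and p-values, 2-decimal display."""
    if not fit.converged:
        raise FitError("cannot tabulate a non-converged fit")
    if np.any(fit.se == 0):
        raise FitError("degenerate zero standard error")
    lo, hi = fit.ci
    rows = []
    for j, name in enumerate(fit.names):
        if name == "intercept" and not include_intercept:
            continue
        rows.append(
            {
                "predictor": name,
                "OR": round(float(fit.odds_ratios[j]), 2),
                "CI_low": round(float(lo[j]), 2),
                "CI_high": round(float(hi[j]), 2),
                "p": format_p(float(fit.p_values[j])),
            }
        )
    return pd.DataFrame(rows)


def hosmer_lemeshow(fit: LogisticFit, X: np.ndarray, y: np.ndarray, n_groups: int = 10):
    """Hosmer-Lemeshow goodness-of-fit on equal-size fitted-probability
    deciles (stable sort breaks ties)."""
    p = special.expit(np.asarray(X, float) @ fit.coef)
    order = np.argsort(p, kind="stable")
    groups = np.array_split(order, n_groups)
    stat = 0.0
    for g in groups:
        obs = float(np.asarray(y)[g].sum())
        exp = float(p[g].sum())
        n_g = len(g)
        if 0 < exp < n_g:
            stat += (obs - exp) ** 2 / (exp * (1 - exp / n_g))
    df = n_groups - 2
    return stat, float(stats.chi2.sf(stat, df)), df
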