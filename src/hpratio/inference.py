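"""Fitting the log-linear biomass-ratio framework to treatment records.

The response is log(H/P) and the predictors are the logs of the four
ecological factors.  The model is fitted by ordinary least squares; the
public coefficients are reported on the framework parameterization

    log(H/P) = eps1 log(a_nut) + eps2 log(a_edi) + eps3 log(mu)
               - eps4 log(theta) + gamma

i.e. ``eps4`` is the *negated* raw coefficient on log(theta), so a positive
``eps4`` means carnivores depress the ratio.

The module reproduces the full inferential battery used with such designs:

* variance inflation factors (collinearity screen),
* all-subsets AIC model selection (Gaussian likelihood, sigma counted as a
  parameter, as in R's ``AIC``),
* residual-resampling bootstrap with direction-aware one-tailed 95%
  intervals (the a-priori signs of the framework fix the tail for each
  explanatory variable; the intercept gets a two-sided interval),
* standardized coefficients (z-scored response and predictors),
* partial-regression leverage analysis (whose slope equals the full-model
  coefficient, the Frisch-Waugh-Lovell identity),
* simple Pearson correlations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .core import DEFAULT_LOG_BASE
from .field import TreatmentRecord

__all__ = [
    "PREDICTORS",
    "EXPECTED_DIRECTIONS",
    "RegressionResult",
    "PartialLeverage",
    "fit_framework",
    "vif",
    "aic_model_selection",
    "bootstrap_ci",
    "standardized_coefficients",
    "partial_leverage",
    "pearson",
]

#: Predictor order used throughout (columns of the design matrix after the
#: intercept).
PREDICTORS = ("a_nut", "a_edi", "mu", "theta")

#: A-priori effect directions on the framework parameterization; they fix
#: which tail of the bootstrap distribution bounds each coefficient away
#: from zero.  Stoichiometric dilution (a_nut) is expected to depress the
#: ratio; edibility, production and (on this parameterization) carnivore
#: abundance carry positive expected signs.
EXPECTED_DIRECTIONS: Mapping[str, str] = {
    "a_nut": "negative",
    "a_edi": "positive",
    "mu": "positive",
    "theta": "positive",
    "gamma": "two-sided",
}

_PARAM_NAMES = ("gamma", "a_nut", "a_edi", "mu", "theta")


def design_matrix(
    records: Sequence[TreatmentRecord], log_base: float = DEFAULT_LOG_BASE
) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) with X = [1, log a_nut, log a_edi, log mu, log theta]."""
    if len(records) == 0:
        raise ValueError("no records")
    ln_b = math.log(log_base)
    rows = []
    y = []
    for r in records:
        vals = (r.a_nut, r.a_edi, r.mu, r.theta)
        if any(v <= 0 for v in vals) or r.h_biomass <= 0 or r.p_biomass <= 0:
            raise ValueError(f"nonpositive value destined for log in record {r}")
        rows.append([1.0] + [math.log(v) / ln_b for v in vals])
        y.append(math.log(r.h_biomass / r.p_biomass) / ln_b)
    return np.asarray(rows), np.asarray(y)


def _to_framework(beta_raw: np.ndarray) -> np.ndarray:
    """Flip the sign of the theta coefficient (raw -> framework eps)."""
    out = beta_raw.copy()
    out[4] = -out[4]
    return out


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS via least squares; raises on singular design."""
    n, p = X.shape
    if n <= p - 1:
        raise ValueError(f"need n > {p - 1} records for {p - 1} predictors, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"singular design matrix (rank {rank} < {p}); "
            "predictors are collinear"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    return beta, fitted, rss


def _gaussian_aic(rss: float, n: int, n_coef: int) -> float:
    """Full Gaussian log-likelihood AIC with sigma counted (k = n_coef + 1)."""
    sigma2 = max(rss, 1e-300) / n
    llf = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    return -2.0 * llf + 2.0 * (n_coef + 1)


@dataclass
class RegressionResult:
    """Fitted framework coefficients with their inferential annotations.

    ``eps_hat`` maps parameter names to estimates on the framework
    parameterization (theta sign-flipped); ``ci`` holds the bootstrap
    one-tailed 95% intervals (two-sided for gamma); ``std_coef`` the
    standardized coefficients; ``vif`` the variance inflation factors.
    """

    gamma_hat: float
    eps_hat: dict[str, float]
    ci: dict[str, tuple[float, float]]
    std_coef: dict[str, float]
    r2: float
    aic: float
    vif: dict[str, float]
    log_base: float
    n_boot: int
    seed: Optional[int]
    n: int
    residuals: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ci.items():
            if lo > hi + 1e-12:
                raise ValueError(f"CI bounds for {name} out of order: ({lo}, {hi})")
        if not -1e-9 <= self.r2 <= 1 + 1e-9:
            raise ValueError(f"r2 out of [0, 1]: {self.r2}")


def fit_framework(
    records: Sequence[TreatmentRecord],
    log_base: float = DEFAULT_LOG_BASE,
    n_boot: int = 1999,
    seed: Optional[int] = 0,
    directions: Optional[Mapping[str, str]] = None,
) -> RegressionResult:
    """OLS fit of the log-linear framework with the full inference battery.

    Requires more records than parameters (n > 5).  R^2 is ordinary
    (unadjusted); the AIC is the Gaussian-likelihood value of the full
    model; confidence intervals come from :func:`bootstrap_ci`.
    """
    X, y = design_matrix(records, log_base)
    beta_raw, fitted, rss = _ols(X, y)
    n = len(y)
    if n <= X.shape[1]:
        raise ValueError(f"need n > {X.shape[1]} records, got {n}")
    eps = _to_framework(beta_raw)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    ci = bootstrap_ci(
        records, n_boot=n_boot, seed=seed, log_base=log_base, directions=directions
    )
    std = standardized_coefficients(records, log_base=log_base)
    return RegressionResult(
        gamma_hat=float(eps[0]),
        eps_hat={name: float(eps[i + 1]) for i, name in enumerate(PREDICTORS)},
        ci=ci,
        std_coef=std,
        r2=r2,
        aic=_gaussian_aic(rss, n, X.shape[1]),
        vif=vif(records, log_base=log_base),
        log_base=log_base,
        n_boot=n_boot,
        seed=seed,
        n=n,
        residuals=y - fitted,
    )


def vif(
    records: Sequence[TreatmentRecord], log_base: float = DEFAULT_LOG_BASE
) -> dict[str, float]:
    """Variance inflation factor 1/(1 - R^2_j) per log-scale predictor.

    Perfectly collinear predictors are reported as ``inf`` rather than
    raising, so the caller sees which predictor is degenerate.
    """
    X, _ = design_matrix(records, log_base)
    out: dict[str, float] = {}
    for j, name in enumerate(PREDICTORS, start=1):
        others = np.delete(X, j, axis=1)
        xj = X[:, j]
        beta, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ beta
        tss = float(np.sum((xj - xj.mean()) ** 2))
        if tss == 0:
            out[name] = float("inf")
            continue
        r2_j = 1.0 - float(np.sum(resid**2)) / tss
        out[name] = float("inf") if r2_j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2_j)
    return out


def aic_model_selection(
    records: Sequence[TreatmentRecord], log_base: float = DEFAULT_LOG_BASE
) -> list[dict]:
    """All 16 predictor subsets ranked by AIC (intercept always included).

    Returns dicts with ``predictors`` (tuple), ``aic``, ``n_coef`` and
    ``rank``; ties in AIC are broken in favour of the smaller model.
    """
    X, y = design_matrix(records, log_base)
    n = len(y)
    results = []
    for size in range(0, len(PREDICTORS) + 1):
        for subset in itertools.combinations(range(len(PREDICTORS)), size):
            cols = [0] + [j + 1 for j in subset]
            Xs = X[:, cols]
            beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
            rss = float(np.sum((y - Xs @ beta) ** 2))
            results.append(
                {
                    "predictors": tuple(PREDICTORS[j] for j in subset),
                    "aic": _gaussian_aic(rss, n, len(cols)),
                    "n_coef": len(cols),
                }
            )
    results.sort(key=lambda d: (d["aic"], d["n_coef"]))
    for rank, d in enumerate(results, start=1):
        d["rank"] = rank
    return results


def bootstrap_ci(
    records: Sequence[TreatmentRecord],
    n_boot: int = 1999,
    seed: Optional[int] = 0,
    log_base: float = DEFAULT_LOG_BASE,
    directions: Optional[Mapping[str, str]] = None,
) -> dict[str, tuple[float, float]]:
    """Residual-resampling bootstrap 95% intervals, direction-aware.

    Leverage-adjusted residuals ``e_i / sqrt(1 - h_ii)`` (the standard
    correction for the downward bias of OLS residual variance, which is
    severe at n = 8 with five coefficients) are centered, resampled with
    replacement, added back to the fitted values, and the model refitted
    ``n_boot`` times.  For each explanatory variable the interval is
    one-tailed according to its a-priori sign
    (:data:`EXPECTED_DIRECTIONS`): ``positive`` effects get (5th
    percentile, maximum), ``negative`` effects (minimum, 95th percentile),
    so the informative bound is the one nearer zero.  The intercept is
    two-sided (2.5th, 97.5th).  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    dirs = dict(EXPECTED_DIRECTIONS)
    if directions:
        dirs.update(directions)
    X, y = design_matrix(records, log_base)
    beta_raw, fitted, _ = _ols(X, y)
    resid = y - fitted
    hat = np.einsum("ij,ji->i", X, np.linalg.pinv(X))
    adjusted = resid / np.sqrt(np.clip(1.0 - hat, 1e-12, None))
    centered = adjusted - adjusted.mean()
    rng = np.random.default_rng(seed)
    n = len(y)
    pinv = np.linalg.pinv(X)
    # all replicates at once: columns are bootstrap responses
    idx = rng.integers(0, n, size=(n, n_boot))
    Ystar = fitted[:, None] + centered[idx]
    betas_raw = pinv @ Ystar  # (5, n_boot)
    betas = betas_raw.copy()
    betas[4] = -betas[4]  # framework parameterization

    out: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(_PARAM_NAMES):
        draws = betas[i]
        d = dirs.get(name, "two-sided")
        if d == "positive":
            lo, hi = np.percentile(draws, 5.0), np.max(draws)
        elif d == "negative":
            lo, hi = np.min(draws), np.percentile(draws, 95.0)
        elif d == "two-sided":
            lo, hi = np.percentile(draws, 2.5), np.percentile(draws, 97.5)
        else:
            raise ValueError(f"unknown direction {d!r} for {name}")
        out[name] = (float(lo), float(hi))
    return out


def standardized_coefficients(
    records: Sequence[TreatmentRecord],
    log_base: float = DEFAULT_LOG_BASE,
    predictors: Optional[Sequence[str]] = None,
) -> dict[str, float]:
    """Coefficients after z-scoring response and predictors (sd with n-1).

    Reported on the framework parameterization (theta sign-flipped); scale-
    free, so they gauge relative effect sizes.  ``predictors`` restricts the
    model to a subset (default: all four); for a single-predictor model the
    standardized coefficient equals the Pearson correlation.
    """
    use = tuple(PREDICTORS) if predictors is None else tuple(predictors)
    if any(p not in PREDICTORS for p in use):
        raise ValueError(f"unknown predictor in {use}; choose from {PREDICTORS}")
    X_full, y = design_matrix(records, log_base)
    cols = [0] + [1 + PREDICTORS.index(p) for p in use]
    X = X_full[:, cols]
    sx = X[:, 1:].std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    if np.any(sx == 0) or sy == 0:
        bad = [use[j] for j in np.where(sx == 0)[0]] or ["response"]
        raise ValueError(f"zero variance in {bad}; standardization undefined")
    beta_raw, *_ = _ols(X, y)
    std = beta_raw[1:] * sx / sy
    out = {}
    for j, name in enumerate(use):
        out[name] = float(-std[j]) if name == "theta" else float(std[j])
    return out


@dataclass(frozen=True)
class PartialLeverage:
    """Partial-regression residual pairs for one predictor.

    ``slope`` (of y_resid on x_resid) equals the full-model raw coefficient
    for the predictor; ``partial_r`` is the partial correlation with its
    two-tailed t-test p-value at df = n - (#predictors + 1).
    """

    predictor: str
    x_resid: np.ndarray
    y_resid: np.ndarray
    partial_r: float
    p_value: float
    slope: float


def partial_leverage(
    records: Sequence[TreatmentRecord],
    predictor: str,
    log_base: float = DEFAULT_LOG_BASE,
) -> PartialLeverage:
    """Partial-regression (added-variable) analysis for one predictor.

    Both the response and the chosen predictor are residualized on the
    remaining predictors (with intercept); the slope of the residual-on-
    residual regression reproduces the full multiple-regression coefficient
    exactly (Frisch-Waugh-Lovell).  The reported slope and residuals are on
    the *raw* design (no theta sign flip), matching what a leverage plot
    displays.
    """
    if predictor not in PREDICTORS:
        raise ValueError(f"unknown predictor {predictor!r}; choose from {PREDICTORS}")
    X, y = design_matrix(records, log_base)
    j = 1 + PREDICTORS.index(predictor)
    others = np.delete(X, j, axis=1)
    xj = X[:, j]
    bx, *_ = np.linalg.lstsq(others, xj, rcond=None)
    by, *_ = np.linalg.lstsq(others, y, rcond=None)
    x_res = xj - others @ bx
    y_res = y - others @ by
    sxx = float(np.sum(x_res**2))
    if sxx <= 1e-30:
        raise np.linalg.LinAlgError(
            f"predictor {predictor!r} is collinear with the others"
        )
    slope = float(np.sum(x_res * y_res) / sxx)
    denom = math.sqrt(sxx * float(np.sum(y_res**2)))
    r = float(np.sum(x_res * y_res) / denom) if denom > 0 else 0.0
    n = len(y)
    df = n - (len(PREDICTORS) + 1)
    if df <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n})")
    r_clamped = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clamped * math.sqrt(df / (1.0 - r_clamped**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return PartialLeverage(
        predictor=predictor,
        x_resid=x_res,
        y_resid=y_res,
        partial_r=r,
        p_value=float(p),
        slope=slope,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson correlation with two-tailed t-test p-value: (r, p, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError(f"need n >= 3, got {len(x)}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), len(x)
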