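"""Distribution fits and standardizations used throughout the analysis.

* Zero-inflated Poisson (ZIP) for pentamer frequency counts: a fraction pi of
  structural zeros mixed with Poisson(lambda) counts.
* Sinh-arcsinh (SHASH) maximum-likelihood transform-to-normal, used to place
  log2(1+count) pentamer frequencies and within-protein Ln(ic50) binding
  predictions on a zero-mean unit-variance Zscale.
* Four-parameter logistic (Hill) and Weibull growth curve least-squares fits
  for cumulative binding curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

_Z95 = 1.959963984540054


class FitError(RuntimeError):
    """A fit could not be computed (degenerate input or non-convergence)."""


# ---------------------------------------------------------------------------
# Zero-inflated Poisson
# ---------------------------------------------------------------------------


@dataclass
class ZipFit:
    lambda_hat: float
    pi_hat: float
    loglik: float
    ci_lambda: tuple[float, float]
    ci_pi: tuple[float, float]
    n: int
    degenerate: bool = False

    def __post_init__(self):
        if not self.degenerate:
            assert self.lambda_hat >= 0 and 0.0 <= self.pi_hat <= 1.0


def _zip_loglik(lam: float, pi: float, n0: int, pos: np.ndarray) -> float:
    """ZIP log-likelihood given zero count n0 and the positive observations."""
    p0 = pi + (1.0 - pi) * math.exp(-lam)
    ll = n0 * math.log(max(p0, 1e-300))
    if pos.size:
        ll += pos.size * math.log(max(1.0 - pi, 1e-300))
        ll += float(np.sum(-lam + pos * math.log(max(lam, 1e-300)) - special.gammaln(pos + 1)))
    return ll


def _profile_pi(lam: float, zero_frac: float) -> float:
    """MLE of pi given lambda (closed form from the zero-fraction equation)."""
    e = math.exp(-lam)
    if e >= 1.0:
        return 0.0
    return min(max((zero_frac - e) / (1.0 - e), 0.0), 1.0 - 1e-12)


def fit_zip(counts: Sequence[int], min_n: int = 10) -> ZipFit:
    """Maximum-likelihood ZIP fit by 1-D profile likelihood on lambda.

    pi given lambda has a closed form; confidence intervals are Wald
    intervals from the observed Fisher information.  An all-zero sample is
    returned as a degenerate fit (pi -> 1, lambda unidentifiable).  When the
    observed zero fraction does not exceed the plain-Poisson expectation
    exp(-mean), the plain Poisson fit is returned with pi = 0.
    """
    x = np.asarray(counts)
    if x.size < min_n:
        raise FitError(f"need at least {min_n} counts, got {x.size}")
    if not np.issubdtype(x.dtype, np.number) or (x < 0).any() or (x != np.floor(x)).any():
        raise ValueError("counts must be non-negative integers")
    x = x.astype(np.int64)
    n = int(x.size)
    n0 = int((x == 0).sum())
    pos = x[x > 0].astype(np.float64)
    if n0 == n:
        return ZipFit(
            lambda_hat=float("nan"), pi_hat=1.0, loglik=0.0,
            ci_lambda=(float("nan"), float("nan")), ci_pi=(1.0, 1.0),
            n=n, degenerate=True,
        )
    mean = float(x.mean())
    zero_frac = n0 / n
    if zero_frac <= math.exp(-mean):
        lam = mean
        ll = _zip_loglik(lam, 0.0, n0, pos)
        se = math.sqrt(lam / n)
        return ZipFit(lam, 0.0, ll,
                      (lam - _Z95 * se, lam + _Z95 * se), (0.0, 0.0), n)

    def nll(lam_log: float) -> float:
        lam = math.exp(lam_log)
        return -_zip_loglik(lam, _profile_pi(lam, zero_frac), n0, pos)

    # lambda of the Poisson part is at least the mean of the positives' scale
    lam0 = float(pos.mean())
    res = optimize.minimize_scalar(
        nll, bracket=(math.log(max(lam0, 1e-6)) - 1.0, math.log(max(lam0, 1e-6))),
        method="brent", options={"xtol": 1e-12},
    )
    lam_hat = math.exp(res.x)
    pi_hat = _profile_pi(lam_hat, zero_frac)
    ll = _zip_loglik(lam_hat, pi_hat, n0, pos)

    # observed Fisher information via numerical Hessian of the joint loglik
    def negll(theta):
        lam, pi = theta
        if lam <= 0 or not (0.0 <= pi < 1.0):
            return np.inf
        return -_zip_loglik(lam, pi, n0, pos)

    h = 1e-5
    theta = np.array([lam_hat, pi_hat])
    hess = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h * max(abs(theta[i]), 1.0)
            ej = np.eye(2)[j] * h * max(abs(theta[j]), 1.0)
            hess[i, j] = (
                negll(theta + ei + ej) - negll(theta + ei - ej)
                - negll(theta - ei + ej) + negll(theta - ei - ej)
            ) / (4.0 * ei[i] * ej[j])
    try:
        cov = np.linalg.inv(hess)
        se_lam = math.sqrt(max(cov[0, 0], 0.0))
        se_pi = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se_lam = se_pi = float("nan")
    return ZipFit(
        lam_hat, pi_hat, ll,
        (lam_hat - _Z95 * se_lam, lam_hat + _Z95 * se_lam),
        (max(pi_hat - _Z95 * se_pi, 0.0), min(pi_hat + _Z95 * se_pi, 1.0)),
        n,
    )


# ---------------------------------------------------------------------------
# SHASH transform-to-normal standardization
# ---------------------------------------------------------------------------


@dataclass
class ShashFit:
    """Sinh-arcsinh (Johnson SU form) transform-to-normal parameters.

    The monotone map to the latent normal scale is
    z = skew + tailweight * asinh((x - location) / scale).
    """

    location: float
    scale: float
    skew: float
    tailweight: float
    fitted_on: str = ""
    method: str = "mle"  # "mle" or "rank" fallback
    # affine post-correction so standardized output has exact mean 0, var 1
    post_shift: float = 0.0
    post_scale: float = 1.0

    def __post_init__(self):
        if self.method == "mle" and (self.scale <= 0 or self.tailweight <= 0):
            raise ValueError("scale and tailweight must be positive")


def _shash_z(x: np.ndarray, loc: float, scale: float, skew: float, tw: float) -> np.ndarray:
    """Monotone map to the latent standard-normal scale."""
    return skew + tw * np.arcsinh((x - loc) / scale)


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse-normal scores (fallback standardization)."""
    x = np.asarray(values, dtype=float)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))


def fit_shash(values: Sequence[float], fitted_on: str = "", min_n: int = 8) -> ShashFit:
    """Fit the sinh-arcsinh family by maximum likelihood.

    Falls back to rank-based inverse-normal scores when the sample is too
    small or the MLE fails.  Constant input is an error: there is nothing to
    standardize.
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if np.ptp(x) == 0.0:
        raise FitError("constant input: standardization undefined")
    if x.size < min_n:
        return _finalize_fit(ShashFit(0, 1, 0, 1, fitted_on, method="rank"), x)
    # fit on internally standardized values so the MLE (and hence the zscores)
    # is exactly equivariant under affine rescaling of the input
    m, s = float(x.mean()), float(x.std())
    u = (x - m) / s
    try:
        with np.errstate(all="ignore"):
            skew, tw, loc_u, scale_u = stats.johnsonsu.fit(u)
        if not (np.isfinite([skew, tw, loc_u, scale_u]).all() and tw > 0 and scale_u > 0):
            raise FitError("non-finite MLE")
        fit = ShashFit(m + s * float(loc_u), s * float(scale_u),
                       float(skew), float(tw), fitted_on)
    except (FitError, RuntimeError, ValueError):
        fit = ShashFit(0, 1, 0, 1, fitted_on, method="rank")
    return _finalize_fit(fit, x)


def _finalize_fit(fit: ShashFit, x: np.ndarray) -> ShashFit:
    """Attach the affine correction giving exact sample mean 0, variance 1."""
    z = _raw_transform(fit, x)
    mu, sd = float(z.mean()), float(z.std())
    if sd == 0.0 or not np.isfinite(sd):
        raise FitError("degenerate transform: zero variance on the normal scale")
    fit.post_shift, fit.post_scale = mu, sd
    return fit


def _raw_transform(fit: ShashFit, x: np.ndarray) -> np.ndarray:
    if fit.method == "rank":
        return rank_inverse_normal(x)
    return _shash_z(x, fit.location, fit.scale, fit.skew, fit.tailweight)


def standardize(values: Sequence[float], fit: ShashFit) -> np.ndarray:
    """Zscale scores: SHASH-transformed values, centered and scaled.

    Strictly monotone in the input, sample mean 0 and variance 1 on the data
    the fit was finalized on.
    """
    x = np.asarray(values, dtype=float)
    return (_raw_transform(fit, x) - fit.post_shift) / fit.post_scale


def shash_standardize(values: Sequence[float], fitted_on: str = "") -> np.ndarray:
    """One-shot fit + standardize."""
    return standardize(values, fit_shash(values, fitted_on=fitted_on))


def zscale_within_protein(
    predictions: pd.DataFrame,
    value_col: str = "ln_ic50",
    group_cols: tuple[str, str] = ("protein_id", "allele"),
    min_n: int = 8,
) -> pd.DataFrame:
    """Standardize Ln(ic50) independently within each (protein, allele) group.

    Adds ``zscore`` and ``zscore_method`` columns.  Groups smaller than
    ``min_n`` (or with MLE failure) use the rank-based fallback and are
    flagged in ``zscore_method``.
    """
    out = predictions.copy()
    out["zscore"] = np.nan
    out["zscore_method"] = ""
    for _, idx in out.groupby(list(group_cols), sort=False).groups.items():
        vals = out.loc[idx, value_col].to_numpy(dtype=float)
        if np.ptp(vals) == 0.0:
            raise FitError(
                f"constant {value_col} in group {_!r}: standardization undefined"
            )
        fit = fit_shash(vals, fitted_on=value_col, min_n=min_n)
        out.loc[idx, "zscore"] = standardize(vals, fit)
        out.loc[idx, "zscore_method"] = fit.method
    return out


def normal_percentile(z: float) -> float:
    """Standard normal CDF as a percentage (z = -1 -> ~15.87, i.e. ~16th pct)."""
    return float(stats.norm.cdf(z) * 100.0)


# ---------------------------------------------------------------------------
# Curve fits: 4-parameter logistic and Weibull growth
# ---------------------------------------------------------------------------


@dataclass
class FourPLFit:
    lower: float
    upper: float
    inflection_x: float
    hill: float
    rmse: float
    n_iterations: int = 0


def four_pl(x: np.ndarray, lower: float, upper: float, inflection_x: float, hill: float) -> np.ndarray:
    """Logistic Hill-coefficient sigmoid between two asymptotes."""
    return lower + (upper - lower) / (1.0 + np.exp(-hill * (np.asarray(x, float) - inflection_x)))


@dataclass
class WeibullFit:
    a: float  # upper asymptote
    b: float  # growth rate (shape)
    c: float  # inflection / scale
    rmse: float


def weibull_growth(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """a * (1 - exp(-(x/c)^b)); passes through the origin."""
    x = np.asarray(x, dtype=float)
    return a * (1.0 - np.exp(-np.power(np.maximum(x, 0.0) / c, b)))


def _multistart_least_squares(residual, starts, bounds):
    best = None
    for p0 in starts:
        try:
            res = optimize.least_squares(
                residual, p0, bounds=bounds, xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except ValueError:
            continue
        if best is None or res.cost < best.cost - 1e-15 or (
            abs(res.cost - best.cost) <= 1e-15
            and np.linalg.norm(res.x) < np.linalg.norm(best.x)
        ):
            best = res
    if best is None or not np.isfinite(best.cost):
        raise FitError("curve fit did not converge from any start")
    return best


def fit_4pl(x: Sequence[float], y: Sequence[float]) -> FourPLFit:
    """Least-squares 4PL fit with 5 deterministic starts from data quantiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 6:
        raise FitError("need at least 6 points for a 4PL fit")
    if np.ptp(y) == 0.0:
        raise FitError("constant response: 4PL fit degenerate")

    lo0, hi0 = float(y.min()), float(y.max())
    span = float(np.ptp(x))
    qs = np.quantile(x, [0.2, 0.35, 0.5, 0.65, 0.8])
    starts = [np.array([lo0, hi0, q, 4.0 / max(span, 1e-9)]) for q in qs]

    def residual(p):
        return four_pl(x, *p) - y

    bounds = ([-np.inf, -np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf, np.inf])
    best = _multistart_least_squares(residual, starts, bounds)
    lower, upper, infl, hill = best.x
    rmse = float(np.sqrt(np.mean((four_pl(x, *best.x) - y) ** 2)))
    return FourPLFit(float(lower), float(upper), float(infl), float(hill), rmse, int(best.nfev))


def fit_weibull_growth(
    x: Sequence[float], y: Sequence[float], bound_a: Optional[float] = None
) -> WeibullFit:
    """Least-squares fit of a*(1-exp(-(x/c)^b)) with quantile-based multistart.

    ``bound_a`` caps the upper asymptote (1.0 for cumulative fractions).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any():
        raise ValueError("Weibull growth requires x >= 0")
    if x.size < 5:
        raise FitError("need at least 5 points for a Weibull growth fit")
    if np.ptp(y) == 0.0:
        raise FitError("constant response: Weibull fit degenerate")
    a_cap = np.inf if bound_a is None else float(bound_a)
    a0 = min(float(y.max()) or 1.0, a_cap)
    xq = np.quantile(x[x > 0], [0.25, 0.4, 0.5, 0.6, 0.75]) if (x > 0).any() else [1.0] * 5
    starts = [np.array([a0 if a0 > 0 else 1.0, b0, max(q, 1e-6)])
              for b0, q in zip((0.8, 1.0, 1.5, 2.0, 3.0), xq)]

    def residual(p):
        return weibull_growth(x, *p) - y

    bounds = ([1e-12, 1e-9, 1e-9], [a_cap, np.inf, np.inf])
    best = _multistart_least_squares(residual, starts, bounds)
    a, b, c = best.x
    rmse = float(np.sqrt(np.mean((weibull_growth(x, *best.x) - y) ** 2)))
    return WeibullFit(float(a), float(b), float(c), rmse)
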