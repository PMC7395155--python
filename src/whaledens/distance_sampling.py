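"""Line-transect detection-function fitting and ship-side density estimation.

Perpendicular sighting distances are modelled with a detection function
g(x) — the probability of detecting a group at distance x from the
trackline, with g(0) = 1 by construction.  Two keys are supported:

* half-normal:  g(x) = exp(-x² / 2σ²)
* hazard-rate:  g(x) = 1 - exp(-(x/σ)^-b)

In the multiple-covariate (MCDS) form the scale is modelled per sighting,
σ_i = exp(β0 + Σ β_j z_ij), on numeric-coded covariates.  Fits maximise the
standard conditional-on-detection likelihood Π g(x_i)/μ_i, where
μ_i = ∫₀ʷ g is the effective half strip width for sighting i.  The average
detectability within the truncated strip is P̂_a = mean_i(μ_i)/w, and the
density estimator is

    D̂ = n · E[s] / (2 · ESW · L)

with n detected groups, mean group size E[s], effective half strip width
ESW = P̂_a·w and effort L; detection on the trackline is assumed certain.
Model selection is by minimum AIC and goodness of fit by the Cramér–von
Mises test on the fitted distance CDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_fprime, approx_hess1

from whaledens.errors import FitError, ValidationError

HALF_NORMAL = "half-normal"
HAZARD_RATE = "hazard-rate"

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(61)


@dataclass
class DetectionFit:
    """A fitted detection function and its summary statistics."""

    key: str
    covariate_names: list[str]
    beta: np.ndarray            # log-scale coefficients, beta[0] = intercept
    shape: float | None         # hazard-rate shape b, None for half-normal
    truncation_w: float         # km
    p_a: float                  # average detectability within the strip
    se_p_a: float
    esw: float                  # effective half strip width, km (= p_a * w)
    log_lik: float
    n_params: int
    aic: float
    beta_cov: np.ndarray | None = None
    cvm_p: float | None = None
    flagged: bool = False

    @property
    def formula(self) -> str:
        return "~ " + (" + ".join(self.covariate_names) or "1")


@dataclass
class DensityEstimate:
    """A density with delta-method CV and provenance."""

    density: float              # whales / km²
    cv: float
    platform: str               # "ship" | "satellite"
    stratum: str = "whole"
    adjusted: bool = False
    components: dict[str, float] = field(default_factory=dict)
    foi_class: str = ""         # satellite only: which FOI class the count used

    def __post_init__(self) -> None:
        if self.density < 0 or self.cv < 0:
            raise ValidationError("density and cv must be >= 0")


def _design_matrix(
    n: int, covariates: Mapping[str, Sequence[float]] | pd.DataFrame | None
) -> tuple[np.ndarray, list[str]]:
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        return np.ones((n, 1)), []
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        z = covariates.to_numpy(dtype=float)
    else:
        names = list(covariates)
        z = np.column_stack([np.asarray(covariates[k], dtype=float) for k in names])
    if z.shape[0] != n:
        raise ValidationError("covariates must have one row per distance")
    return np.column_stack([np.ones(n), z]), names


def _g(key: str, x: np.ndarray, sigma: np.ndarray, shape: float | None) -> np.ndarray:
    if key == HALF_NORMAL:
        return np.exp(-(x**2) / (2.0 * sigma**2))
    # hazard-rate; g(0) = 1 by continuity (the hazard blows up at the trackline)
    x, sigma = np.broadcast_arrays(np.asarray(x, float), np.asarray(sigma, float))
    ratio = np.where(x > 0, x / sigma, 1.0)
    with np.errstate(over="ignore"):
        hazard = ratio ** (-shape)
    return np.where(x > 0, 1.0 - np.exp(-hazard), 1.0)


def _mu(key: str, sigma: np.ndarray, w: float, shape: float | None) -> np.ndarray:
    """Effective half strip width ∫₀ʷ g(x) dx per observation."""
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    if key == HALF_NORMAL:
        return sigma * np.sqrt(np.pi / 2.0) * special.erf(w / (sigma * np.sqrt(2.0)))
    # Gauss-Legendre on [0, w]; the hazard-rate integrand is smooth on (0, w]
    xs = 0.5 * w * (_GL_NODES + 1.0)
    gx = _g(HAZARD_RATE, xs[None, :], sigma[:, None], shape)
    return 0.5 * w * gx @ _GL_WEIGHTS


def _unpack(theta: np.ndarray, key: str, n_cov: int) -> tuple[np.ndarray, float | None]:
    beta = theta[: n_cov + 1]
    shape = float(np.exp(theta[-1])) + 1.0 if key == HAZARD_RATE else None
    return beta, shape


def _negloglik(theta: np.ndarray, key: str, x: np.ndarray, Z: np.ndarray, w: float) -> float:
    beta, shape = _unpack(theta, key, Z.shape[1] - 1)
    sigma = np.exp(Z @ beta)
    if not np.all(np.isfinite(sigma)) or np.any(sigma <= 0):
        return 1e12
    g = _g(key, x, sigma, shape)
    mu = _mu(key, sigma, w, shape)
    if np.any(g <= 0) or np.any(mu <= 0):
        return 1e12
    val = -(np.sum(np.log(g)) - np.sum(np.log(mu)))
    return val if np.isfinite(val) else 1e12


def fit_detection(
    distances: Sequence[float],
    covariates: Mapping[str, Sequence[float]] | pd.DataFrame | None = None,
    key: str = HALF_NORMAL,
    truncation_w: float | None = None,
    n_starts: int = 3,
) -> DetectionFit:
    """Maximum-likelihood fit of a detection function to perpendicular distances.

    Parameters
    ----------
    distances:
        Perpendicular distances in km; values beyond ``truncation_w`` are
        right-truncated (dropped together with their covariate rows).
    covariates:
        Optional numeric-coded scale covariates (ordinal scales as numeric
        levels).  The scale is log-linear in the covariates.
    key:
        ``"half-normal"`` or ``"hazard-rate"``.
    truncation_w:
        Right-truncation distance in km; defaults to the maximum observed
        distance.
    n_starts:
        Number of multi-start initialisations (the hazard-rate likelihood
        can be multimodal).
    """
    if key not in (HALF_NORMAL, HAZARD_RATE):
        raise ValidationError(f"unknown key {key!r}")
    x = np.asarray(distances, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("need at least 2 distances")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValidationError("distances must be finite and >= 0")
    w = float(truncation_w) if truncation_w is not None else float(x.max())
    if w <= 0:
        raise ValidationError("truncation_w must be > 0")
    keep = x <= w
    Z_full, names = _design_matrix(len(x), covariates)
    x, Z = x[keep], Z_full[keep]
    if len(np.unique(x)) < 2:
        raise FitError("degenerate data: fewer than 2 distinct distances")

    n_cov = Z.shape[1] - 1
    # start heuristics: sd of distances sets the scale; fixed multipliers
    sigma0 = max(np.std(x), 1e-3)
    starts = []
    for mult in (1.0, 0.5, 2.0)[:n_starts]:
        theta0 = np.zeros(n_cov + 1 + (1 if key == HAZARD_RATE else 0))
        theta0[0] = np.log(sigma0 * mult)
        if key == HAZARD_RATE:
            theta0[-1] = np.log(2.0 - 1.0)  # b = 2
        starts.append(theta0)

    best = None
    traces = []
    for theta0 in starts:
        res = optimize.minimize(
            _negloglik,
            theta0,
            args=(key, x, Z, w),
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-10},
        )
        traces.append(f"start {theta0}: {res.message} nll={res.fun:.6f}")
        if res.fun < 1e11 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError("detection-function fit failed to converge:\n" + "\n".join(traces))

    theta = best.x
    if n_cov == 0:
        # polish the scale to machine precision so the score equation closes
        if key == HALF_NORMAL:
            def score(sig):
                # dl/dσ = Σx²/σ³ − n·μ'(σ)/μ(σ), closed form under truncation
                z = w / (sig * np.sqrt(2.0))
                mu = sig * np.sqrt(np.pi / 2.0) * special.erf(z)
                dmu = np.sqrt(np.pi / 2.0) * special.erf(z) - (w / sig) * np.exp(-z * z)
                return np.sum(x**2) / sig**3 - len(x) * dmu / mu

            sig_hat = np.exp(theta[0])
            lo, hi = 0.5 * sig_hat, 2.0 * sig_hat
            if score(lo) * score(hi) < 0:
                root = optimize.brentq(score, lo, hi, xtol=1e-14, rtol=1e-15)
                theta = theta.copy()
                theta[0] = np.log(root)
        if key == HAZARD_RATE:
            res2 = optimize.minimize(
                _negloglik, theta, args=(key, x, Z, w), method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 2000},
            )
            if res2.fun <= _negloglik(theta, key, x, Z, w):
                theta = res2.x

    beta, shape = _unpack(theta, key, n_cov)
    sigma = np.exp(Z @ beta)
    mu = _mu(key, sigma, w, shape)
    p_a = float(np.mean(mu) / w)
    log_lik = -_negloglik(theta, key, x, Z, w)
    n_params = len(theta)

    # delta-method SE of P_a from the inverse observed information
    se_p_a = float("nan")
    cov = None
    try:
        hess = approx_hess1(theta, _negloglik, args=(key, x, Z, w))
        cov = np.linalg.inv(hess)

        def p_a_of(t):
            b, s = _unpack(t, key, n_cov)
            return float(np.mean(_mu(key, np.exp(Z @ b), w, s)) / w)

        grad = approx_fprime(theta, p_a_of).ravel()
        var = float(grad @ cov @ grad)
        if var >= 0:
            se_p_a = float(np.sqrt(var))
    except np.linalg.LinAlgError:
        pass

    return DetectionFit(
        key=key,
        covariate_names=names,
        beta=beta,
        shape=shape,
        truncation_w=w,
        p_a=p_a,
        se_p_a=se_p_a,
        esw=p_a * w,
        log_lik=log_lik,
        n_params=n_params,
        aic=2.0 * n_params - 2.0 * log_lik,
        beta_cov=cov,
        flagged=(p_a <= 0.01) or not np.isfinite(se_p_a),
    )


def detection_cdf(fit: DetectionFit, x: np.ndarray,
                  Z: np.ndarray | None = None) -> np.ndarray:
    """Fitted CDF of perpendicular distance, averaged over covariate rows."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if Z is None:
        Z = np.ones((1, 1))
    sigma = np.exp(Z @ fit.beta)
    mu_w = _mu(fit.key, sigma, fit.truncation_w, fit.shape)
    out = np.empty_like(x)
    for j, xv in enumerate(x):
        xv = min(max(xv, 0.0), fit.truncation_w)
        mu_x = _mu(fit.key, sigma, xv, fit.shape) if xv > 0 else np.zeros_like(mu_w)
        out[j] = np.mean(mu_x / mu_w)
    return out


def cvm_test(
    fit: DetectionFit,
    distances: Sequence[float],
    covariates: Mapping[str, Sequence[float]] | pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Cramér–von Mises goodness-of-fit test of the fitted distance CDF.

    Returns ``(statistic, p_value)`` using the asymptotic CvM distribution
    (no correction for estimated parameters, so the p-value is approximate
    and mildly conservative toward good fit).
    """
    x = np.asarray(distances, dtype=float)
    if len(x) < 5:
        raise ValidationError("Cramér–von Mises test requires at least 5 distances")
    Z, _ = _design_matrix(len(x), covariates)
    keep = x <= fit.truncation_w
    x, Z = x[keep], Z[keep]
    res = stats.cramervonmises(x, lambda q: detection_cdf(fit, q, Z))
    return float(res.statistic), float(res.pvalue)


def select_model(fits: Sequence[DetectionFit]) -> tuple[DetectionFit, pd.DataFrame]:
    """Rank converged fits by AIC and return the minimum-AIC fit.

    Fits with implausible parameters (P̂_a <= 0.01 or an undefined standard
    error) are flagged in the table and skipped when choosing the winner,
    unless every candidate is flagged.
    """
    if not fits:
        raise ValidationError("no fitted models to select from")
    rows = [
        {
            "key": f.key,
            "formula": f.formula,
            "cvm_p": f.cvm_p,
            "p_a": f.p_a,
            "se_p_a": f.se_p_a,
            "esw": f.esw,
            "aic": f.aic,
            "flagged": f.flagged,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    candidates = [f for f in fits if not f.flagged] or list(fits)
    best = min(candidates, key=lambda f: f.aic)
    return best, table


def mean_group_size(group_sizes: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean group size and its CV, (sd/√n)/mean."""
    s = np.asarray(group_sizes, dtype=float)
    if len(s) == 0:
        raise ValidationError("no sightings")
    mean = float(s.mean())
    if len(s) == 1 or s.std(ddof=1) == 0:
        return mean, 0.0
    return mean, float((s.std(ddof=1) / np.sqrt(len(s))) / mean)


def ship_density(
    n_groups: int,
    mean_group_size: float,
    esw: float,
    effort_L: float,
    cv_components: Mapping[str, float] | None = None,
    stratum: str = "whole",
) -> DensityEstimate:
    """Along-track density D̂ = n·E[s] / (2·ESW·L) with quadrature CV.

    ``cv_components`` carries the named CV components (encounter rate,
    detection/ESW, group size); the total CV is their root-sum-of-squares.
    """
    if esw <= 0 or effort_L <= 0:
        raise ValidationError("esw and effort_L must be > 0")
    if n_groups < 0 or mean_group_size < 0:
        raise ValidationError("counts and group size must be >= 0")
    density = n_groups * mean_group_size / (2.0 * esw * effort_L)
    comps = dict(cv_components or {})
    cv = float(np.sqrt(sum(v * v for v in comps.values())))
    return DensityEstimate(
        density=float(density), cv=cv, platform="ship",
        stratum=stratum, adjusted=False, components=comps,
    )


def encounter_rate_cv(n_per_transect: Sequence[float], lengths: Sequence[float]) -> float:
    """Empirical CV of the encounter rate n/L from between-transect variability.

    Standard weighted estimator: var(n/L) = Σ l_k (n_k/l_k − n/L)² / (L (K−1)).
    """
    n = np.asarray(n_per_transect, dtype=float)
    l = np.asarray(lengths, dtype=float)
    if len(n) != len(l) or len(n) < 2:
        raise ValidationError("need counts and lengths for at least 2 transects")
    if np.any(l <= 0):
        raise ValidationError("transect lengths must be > 0")
    L, N = l.sum(), n.sum()
    if N == 0:
        raise ValidationError("no sightings")
    rate = N / L
    var = np.sum(l * (n / l - rate) ** 2) / (L * (len(n) - 1))
    return float(np.sqrt(var) / rate)
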