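"""Parameter estimation and model comparison for the psychometric model.

Two estimation routes are provided:

* **Least squares** (:func:`fit_nls`): minimises the sum of squared
  deviations between observed per-condition choice proportions and the
  model's predicted performance, with the near-miss exponent ``beta`` either
  fixed (Weber's law when fixed at 1) or estimated freely.  The two nested
  variants are compared with AIC and an extra-sum-of-squares F test with one
  numerator degree of freedom (:func:`compare_nested`).

* **Bayesian** (:func:`fit_bayes`): samples the posterior of (threshold,
  slope, lapse) under a binomial likelihood with informative priors — a
  Beta(2, 10) on the lapse rate, a Normal(1, 0.5) on the threshold and a
  log-normal on the slope — at a fixed ``beta``, via an affine-invariant
  ensemble MCMC sampler.

Least squares on proportions (rather than a binomial GLM) mirrors the
classical analysis workflow these data were designed for; a
binomial-likelihood point fit is available as an opt-in alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .choice_data import PerformanceRecord
from .exceptions import ComparisonError, DomainError, FitError
from .psychometric import PsychometricParams

__all__ = [
    "FitResult",
    "ModelComparison",
    "PriorSpec",
    "PosteriorSummary",
    "fit_nls",
    "model_aic",
    "compare_nested",
    "fit_bayes",
    "paired_param_test",
]

_LN2 = math.log(2.0)

#: Box bounds for the optimiser, in the internal parameterisation
#: (log m, log s, lapse, beta).
_DEFAULT_BOUNDS = {
    "log_m": (-18.0, 18.0),
    "log_s": (-18.0, 18.0),
    "lapse": (0.0, 0.5),
    "beta": (-2.0, 8.0),
}

#: AIC sentinel returned when RSS underflows to zero (perfect fit).
AIC_PERFECT_FIT = -1.0e12


@dataclass(frozen=True)
class FitResult:
    """Outcome of one nonlinear least-squares psychometric fit."""

    params: PsychometricParams
    beta_mode: str  # "free" or "fixed(<value>)"
    rss: float
    n_points: int
    n_params: int
    aic: float
    beta_ci: tuple[float, float] | None
    converged: bool
    start_used: tuple[float, ...]
    data_key: tuple = field(default=(), compare=False, repr=False)
    param_se: Mapping[str, float] = field(default_factory=dict, compare=False, repr=False)
    message: str = field(default="", compare=False)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "m": p.m,
            "s": p.s,
            "lapse": p.lapse,
            "beta": p.beta,
            "scale": p.scale,
            "beta_mode": self.beta_mode,
            "rss": self.rss,
            "n_points": self.n_points,
            "n_params": self.n_params,
            "aic": self.aic,
            "beta_ci": list(self.beta_ci) if self.beta_ci else None,
            "converged": self.converged,
            "start_used": list(self.start_used),
            "message": self.message,
        }


@dataclass(frozen=True)
class ModelComparison:
    """Nested comparison of a free-beta fit against the beta=1 reduction.

    ``delta_aic = AIC(reduced) - AIC(full)``: positive values favour the
    full (near-miss) model.  The F statistic is the extra-sum-of-squares
    test with (1, n - n_params_full) degrees of freedom.
    """

    delta_aic: float
    f_stat: float
    df1: int
    df2: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "delta_aic": self.delta_aic,
            "f_stat": self.f_stat,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class PriorSpec:
    """Informative priors for the Bayesian psychometric fit.

    ``slope_prior_on`` selects whether (slope_loc, slope_scale) parameterise
    the underlying normal on ln(s) (``"log"``, the conventional reading) or
    the mean/sd of s itself (``"raw"``).
    """

    lapse_a: float = 2.0
    lapse_b: float = 10.0
    threshold_mean: float = 1.0
    threshold_sd: float = 0.5
    slope_loc: float = 2.0
    slope_scale: float = 1.0
    slope_prior_on: Literal["log", "raw"] = "log"

    def __post_init__(self) -> None:
        for name in ("lapse_a", "lapse_b", "threshold_sd", "slope_scale"):
            if getattr(self, name) <= 0:
                raise DomainError(f"prior hyper-parameter {name} must be positive")

    def slope_log_params(self) -> tuple[float, float]:
        """(mu, sigma) of the normal on ln(s) implied by the spec."""
        if self.slope_prior_on == "log":
            return self.slope_loc, self.slope_scale
        # moment-match a log-normal with mean slope_loc, sd slope_scale
        cv2 = (self.slope_scale / self.slope_loc) ** 2
        sigma2 = math.log1p(cv2)
        mu = math.log(self.slope_loc) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter posterior summaries from the Bayesian fit."""

    mean: Mapping[str, float]
    sd: Mapping[str, float]
    quantiles: Mapping[str, Mapping[float, float]]
    n_samples: int
    seed: int
    acceptance_rate: float
    ess: Mapping[str, float]
    beta: float
    scale: float
    warnings: tuple[str, ...] = ()

    @property
    def params(self) -> PsychometricParams:
        """Posterior-mean parameter tuple (lapse clipped into the model domain)."""
        return PsychometricParams(
            m=self.mean["m"],
            s=self.mean["s"],
            lapse=min(self.mean["lapse"], 0.499999),
            beta=self.beta,
            scale=self.scale,
        )

    def to_dict(self) -> dict:
        return {
            "mean": dict(self.mean),
            "sd": dict(self.sd),
            "quantiles": {k: {str(q): v for q, v in qs.items()} for k, qs in self.quantiles.items()},
            "n_samples": self.n_samples,
            "seed": self.seed,
            "acceptance_rate": self.acceptance_rate,
            "ess": dict(self.ess),
            "beta": self.beta,
            "scale": self.scale,
            "warnings": list(self.warnings),
        }


def _design_arrays(
    records: Sequence[PerformanceRecord],
    zero_substitute: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(diff, mean, perf, n_high, n_total) arrays from performance records."""
    if not records:
        raise FitError("no performance records to fit")
    diff = np.array([r.x - r.a for r in records], dtype=float)
    mean = np.array([(r.x + r.a) / 2.0 for r in records], dtype=float)
    perf = np.array([r.performance for r in records], dtype=float)
    n_high = np.array([r.n_high for r in records], dtype=float)
    n_total = np.array([r.n_total for r in records], dtype=float)
    if zero_substitute is not None:
        # Historical compatibility: zero intensity entered as a tiny epsilon.
        diff = np.where(diff == 0.0, zero_substitute * mean, diff)
    return diff, mean, perf, n_high, n_total


def _predict(theta: np.ndarray, diff: np.ndarray, mean: np.ndarray, scale: float) -> np.ndarray:
    log_m, log_s, lapse, beta = theta
    m, s = math.exp(log_m), math.exp(log_s)
    intensity = scale * diff * mean ** (-beta)
    k = 2.0 * m * s / _LN2
    # lambda = m * ln2^(-1/k), computed in logs and capped so extreme
    # optimiser excursions degrade to a flat curve instead of overflowing
    log_lam = min(log_m - math.log(_LN2) / k, 700.0)
    lam = math.exp(log_lam)
    with np.errstate(over="ignore"):
        f = -np.expm1(-((intensity / lam) ** k))
    return 0.5 + (0.5 - lapse / 2.0) * f


def _data_key(records: Sequence[PerformanceRecord]) -> tuple:
    return tuple(sorted((r.x, r.a, r.n_high, r.n_total) for r in records))


def fit_nls(
    records: Sequence[PerformanceRecord],
    beta_mode: float | Literal["free"] = 1.0,
    start: tuple[float, float, float, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    scale: float = 1.0,
    n_restarts: int = 5,
    zero_substitute: float | None = None,
    likelihood: Literal["gaussian", "binomial"] = "gaussian",
) -> FitResult:
    """Fit the psychometric model to performance records by least squares.

    Parameters
    ----------
    records : sequence of PerformanceRecord
        Per-condition choice proportions; needs at least one more record
        than free parameters.
    beta_mode : float or "free"
        A number fixes the near-miss exponent at that value (1.0 = Weber's
        law); ``"free"`` estimates it from the data with a 95% asymptotic
        confidence interval.
    start : tuple, optional
        Starting values ``(m, s, lapse, beta)`` on the natural scale.
        Defaults to m = median observed intensity, s = 2/m, lapse = 0.1 and
        beta at its fixed value (or 1 when free).
    bounds : mapping, optional
        Override the default box bounds per parameter name
        (``log_m, log_s, lapse, beta``).
    scale : float
        Fixed intensity display factor; absorbed by m and s, so it changes
        the reported parameterisation but not the fitted curve.
    n_restarts : int
        Number of jittered restarts around the start (deterministic,
        internally seeded); the lowest-RSS solution wins, ties broken by the
        beta nearest 1.
    zero_substitute : float, optional
        When set (e.g. 1e-6), equal-concentration conditions enter with this
        relative intensity instead of exactly zero, reproducing historical
        analysis scripts bit-for-bit.
    likelihood : {"gaussian", "binomial"}
        "gaussian" (default) is ordinary least squares on proportions.
        "binomial" maximises the binomial log-likelihood instead; RSS and
        AIC are still reported from the squared residuals for comparability.
    """
    free_beta = beta_mode == "free"
    n_params = 4 if free_beta else 3
    if len(records) < n_params + 1:
        raise FitError(
            f"need at least {n_params + 1} records for a {n_params}-parameter fit, "
            f"got {len(records)}"
        )
    if scale <= 0:
        raise DomainError(f"scale={scale} must be positive")
    diff, mean, perf, n_high, n_total = _design_arrays(records, zero_substitute)
    if np.ptp(diff * mean ** (-1.0)) == 0.0:
        raise FitError("degenerate design: all conditions have equal relative intensity")

    beta_fixed = 1.0 if free_beta else float(beta_mode)
    beta0 = 1.0 if free_beta else beta_fixed
    if start is None:
        i0 = scale * diff * mean ** (-beta0)
        m0 = float(np.median(i0[i0 > 0]))
        start = (m0, 2.0 / m0, 0.1, beta0)
    m0, s0, l0, b0 = start
    if m0 <= 0 or s0 <= 0:
        raise DomainError("start values for m and s must be positive")
    theta0 = np.array([math.log(m0), math.log(s0), l0, b0])

    bnds = dict(_DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds["log_m"][0], bnds["log_s"][0], bnds["lapse"][0], bnds["beta"][0]])
    hi = np.array([bnds["log_m"][1], bnds["log_s"][1], bnds["lapse"][1], bnds["beta"][1]])
    if not free_beta:
        lo[3] = hi[3] = beta_fixed
        theta0[3] = beta_fixed
    theta0 = np.clip(theta0, lo, hi)
    # least_squares requires strictly increasing bounds; widen the pinned
    # beta coordinate infinitesimally.
    eps_pin = 1e-12
    lo_ls = lo.copy()
    hi_ls = hi.copy()
    if not free_beta:
        lo_ls[3] -= eps_pin
        hi_ls[3] += eps_pin

    if likelihood == "gaussian":
        def residuals(theta):
            return perf - _predict(theta, diff, mean, scale)

        def objective(theta):
            r = residuals(theta)
            return float(r @ r)
    elif likelihood == "binomial":
        def objective(theta):
            p = np.clip(_predict(theta, diff, mean, scale), 1e-12, 1 - 1e-12)
            return float(-np.sum(n_high * np.log(p) + (n_total - n_high) * np.log1p(-p)))
    else:
        raise DomainError(f"unknown likelihood {likelihood!r}")

    rng = np.random.default_rng(0)  # fixed: restarts are part of the algorithm
    starts = [theta0]
    for _ in range(n_restarts):
        jit = theta0 + rng.normal(0.0, [0.5, 0.5, 0.05, 0.5 if free_beta else 0.0], 4)
        starts.append(np.clip(jit, lo, hi))
    if free_beta:
        # Seed the free fit from the Weber's-law solution so the nested
        # model's RSS is always attainable.
        try:
            reduced = fit_nls(
                records, beta_mode=1.0, scale=scale, n_restarts=2,
                zero_substitute=zero_substitute, likelihood=likelihood,
            )
            p = reduced.params
            starts.append(np.array([math.log(p.m), math.log(p.s), p.lapse, 1.0]))
        except FitError:
            pass

    best = None
    for th0 in starts:
        if likelihood == "gaussian":
            try:
                res = optimize.least_squares(
                    residuals, th0, bounds=(lo_ls, hi_ls), method="trf",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            cand = (float(res.cost * 2.0), res.x, res.status > 0, res)
        else:
            res = optimize.minimize(
                objective, th0, method="L-BFGS-B",
                bounds=list(zip(lo_ls, hi_ls)),
            )
            r = perf - _predict(res.x, diff, mean, scale)
            cand = (float(r @ r), res.x, res.success, res)
        if best is None:
            best = cand
        else:
            better = cand[0] < best[0] - 1e-14
            tied = abs(cand[0] - best[0]) <= 1e-14
            if better or (tied and abs(cand[1][3] - 1.0) < abs(best[1][3] - 1.0)):
                best = cand
    if best is None:
        raise FitError("all optimisation starts failed")

    rss, theta_hat, converged, res = best
    m_hat, s_hat = math.exp(theta_hat[0]), math.exp(theta_hat[1])
    lapse_hat = float(np.clip(theta_hat[2], 0.0, 0.5 - 1e-12))
    beta_hat = float(theta_hat[3]) if free_beta else beta_fixed
    at_lapse_bound = theta_hat[2] >= bnds["lapse"][1] - 1e-9
    message = "lapse estimate at upper bound" if at_lapse_bound else ""

    n = len(records)
    beta_ci = None
    param_se: dict[str, float] = {}
    if free_beta:
        beta_ci, param_se = _asymptotic_beta_ci(
            theta_hat, diff, mean, perf, scale, rss, n, n_params
        )
    aic = model_aic_from_rss(rss, n, n_params)
    params = PsychometricParams(m=m_hat, s=s_hat, lapse=lapse_hat, beta=beta_hat, scale=scale)
    return FitResult(
        params=params,
        beta_mode="free" if free_beta else f"fixed({beta_fixed:g})",
        rss=rss,
        n_points=n,
        n_params=n_params,
        aic=aic,
        beta_ci=beta_ci,
        converged=bool(converged),
        start_used=tuple(start),
        data_key=_data_key(records),
        param_se=param_se,
        message=message,
    )


def _asymptotic_beta_ci(theta_hat, diff, mean, perf, scale, rss, n, n_params):
    """95% CI for beta from the asymptotic covariance at the solution."""
    def predict_vec(theta):
        return _predict(theta, diff, mean, scale)

    # central-difference Jacobian of predictions wrt the internal parameters
    h = 1e-6
    jac = np.empty((len(diff), 4))
    for j in range(4):
        tp, tm = theta_hat.copy(), theta_hat.copy()
        tp[j] += h
        tm[j] -= h
        jac[:, j] = (predict_vec(tp) - predict_vec(tm)) / (2 * h)
    dof = n - n_params
    if dof <= 0:
        return None, {}
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        return None, {}
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    tcrit = stats.t.ppf(0.975, dof)
    beta_hat = theta_hat[3]
    ci = (float(beta_hat - tcrit * se[3]), float(beta_hat + tcrit * se[3]))
    names = ("log_m", "log_s", "lapse", "beta")
    return ci, {k: float(v) for k, v in zip(names, se)}


def model_aic_from_rss(rss: float, n: int, n_params: int) -> float:
    """Gaussian-likelihood AIC: ``n ln(2 pi RSS / n) + n + 2 (n_params + 1)``.

    The error variance counts as an estimated parameter, so two nested fits
    with identical RSS and one parameter's difference differ by exactly 2.
    A zero RSS (perfect fit) returns a large negative sentinel.
    """
    if rss < 0:
        raise DomainError(f"rss={rss} must be non-negative")
    if n < 1:
        raise DomainError("n must be positive")
    if rss == 0.0:
        return AIC_PERFECT_FIT
    return n * math.log(2.0 * math.pi * rss / n) + n + 2.0 * (n_params + 1)


def model_aic(fit: FitResult) -> float:
    """AIC of a fit under the package's Gaussian log-likelihood convention."""
    return model_aic_from_rss(fit.rss, fit.n_points, fit.n_params)


def compare_nested(full: FitResult, reduced: FitResult, rss_tol: float = 1e-8) -> ModelComparison:
    """Compare a free-beta fit (full) with its beta-fixed reduction.

    ``delta_aic = AIC(reduced) - AIC(full)`` and the extra-sum-of-squares F
    statistic ``(RSS_r - RSS_f) / (RSS_f / (n - p_f))`` with
    (1, n - p_f) degrees of freedom.  Both fits must have been produced from
    the same records.
    """
    if full.data_key != reduced.data_key or full.n_points != reduced.n_points:
        raise ComparisonError("fits were not produced from the same records")
    if full.n_params != reduced.n_params + 1:
        raise ComparisonError(
            f"not a 1-df nested pair: n_params {full.n_params} vs {reduced.n_params}"
        )
    if reduced.rss < full.rss - rss_tol:
        raise ComparisonError(
            f"reduced-model RSS {reduced.rss} below full-model RSS {full.rss}: "
            "fits are not nested or the full fit did not converge"
        )
    n = full.n_points
    df2 = n - full.n_params
    if df2 <= 0:
        raise ComparisonError("no residual degrees of freedom for the F test")
    extra = max(reduced.rss - full.rss, 0.0)
    if full.rss == 0.0:
        f_stat = math.inf if extra > 0 else 0.0
    else:
        f_stat = extra / (full.rss / df2)
    p_value = float(stats.f.sf(f_stat, 1, df2)) if math.isfinite(f_stat) else 0.0
    return ModelComparison(
        delta_aic=reduced.aic - full.aic,
        f_stat=float(f_stat),
        df1=1,
        df2=df2,
        p_value=p_value,
    )


# ---------------------------------------------------------------------------
# Bayesian estimation
# ---------------------------------------------------------------------------

_PARAM_NAMES = ("m", "s", "lapse")
_QUANTS = (0.025, 0.25, 0.5, 0.75, 0.975)


def _log_prior(theta: np.ndarray, priors: PriorSpec) -> float:
    m, s, lapse = theta
    if m <= 0 or s <= 0 or not 0.0 < lapse < 1.0:
        return -math.inf
    mu, sigma = priors.slope_log_params()
    lp = stats.norm.logpdf(m, priors.threshold_mean, priors.threshold_sd)
    lp += stats.norm.logpdf(math.log(s), mu, sigma) - math.log(s)
    lp += stats.beta.logpdf(lapse, priors.lapse_a, priors.lapse_b)
    return float(lp)


def fit_bayes(
    records: Sequence[PerformanceRecord],
    priors: PriorSpec | None = None,
    n_samples: int = 5000,
    seed: int = 0,
    beta: float = 1.0,
    scale: float = 1.0,
    n_walkers: int = 10,
    n_burn: int = 1000,
    zero_substitute: float | None = None,
) -> PosteriorSummary:
    """Sample the posterior of (m, s, lapse) at fixed beta.

    The likelihood is binomial: per condition, ``n_high`` successes in
    ``n_total`` visits with success probability given by the psychometric
    model.  Sampling uses the emcee affine-invariant ensemble sampler with
    ``n_walkers`` walkers, ``n_burn`` discarded adaptation steps per walker
    and enough retained steps for at least ``n_samples`` draws.  Fully
    reproducible given ``seed``.

    Passing an empty record collection samples the prior itself, which is
    useful for validating the prior specification.
    """
    import emcee

    if priors is None:
        priors = PriorSpec()
    if n_samples < 1:
        raise DomainError("n_samples must be positive")
    records = list(records)
    if records:
        diff, mean, _, n_high, n_total = _design_arrays(records, zero_substitute)
        intensity = scale * diff * mean ** (-beta)
    else:
        intensity = n_high = n_total = None

    def log_prob(theta):
        lp = _log_prior(theta, priors)
        if not math.isfinite(lp):
            return -math.inf
        if intensity is None:
            return lp
        m, s, lapse = theta
        k = 2.0 * m * s / _LN2
        lam = m * _LN2 ** (-1.0 / k)
        with np.errstate(over="ignore"):
            f = -np.expm1(-((intensity / lam) ** k))
        p = np.clip(0.5 + (0.5 - lapse / 2.0) * f, 1e-12, 1.0 - 1e-12)
        ll = np.sum(n_high * np.log(p) + (n_total - n_high) * np.log1p(-p))
        if not math.isfinite(ll):
            return -math.inf
        return lp + float(ll)

    rng = np.random.default_rng(seed)
    mu, sigma = priors.slope_log_params()
    if records:
        # Start the ensemble in a tight ball around the least-squares point
        # estimate (the usual ensemble-sampler initialisation); walkers then
        # only need to explore the posterior, not find it.
        try:
            point = fit_nls(records, beta_mode=beta, scale=scale,
                            zero_substitute=zero_substitute, n_restarts=2).params
            center = np.array([point.m, point.s, min(max(point.lapse, 0.02), 0.8)])
        except (FitError, DomainError):
            center = np.array([priors.threshold_mean, math.exp(mu), 0.1])
        init = center * np.exp(rng.normal(0.0, 0.05, size=(n_walkers, 3)))
        init[:, 2] = np.clip(init[:, 2], 1e-4, 0.95)
    else:
        # no data: sample the prior, so start from prior draws
        init = np.column_stack(
            [
                np.abs(rng.normal(priors.threshold_mean, priors.threshold_sd, n_walkers)) + 1e-6,
                np.exp(rng.normal(mu, sigma, n_walkers)),
                rng.beta(priors.lapse_a, priors.lapse_b, n_walkers),
            ]
        )
    sampler = emcee.EnsembleSampler(n_walkers, 3, log_prob)
    n_steps = n_burn + math.ceil(n_samples / n_walkers)
    state = emcee.State(init, random_state=np.random.RandomState(seed & 0x7FFFFFFF))
    sampler.run_mcmc(state, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn)  # (steps, walkers, 3)
    flat = chain.reshape(-1, 3)[:n_samples]
    acceptance = float(np.mean(sampler.acceptance_fraction))

    warnings: list[str] = []
    if not 0.1 <= acceptance <= 0.9:
        warnings.append(
            f"mean acceptance rate {acceptance:.3f} outside [0.1, 0.9]"
        )
    ess: dict[str, float] = {}
    import logging

    autocorr_logger = logging.getLogger("emcee.autocorr")
    old_level = autocorr_logger.level
    autocorr_logger.setLevel(logging.ERROR)  # short-chain caveats are expected
    try:
        for j, name in enumerate(_PARAM_NAMES):
            try:
                tau = emcee.autocorr.integrated_time(chain[:, :, j], quiet=True)
                ess[name] = float(flat.shape[0] / max(float(tau[0]), 1.0))
            except Exception:
                ess[name] = float("nan")
    finally:
        autocorr_logger.setLevel(old_level)
    if any(e == 0 for e in ess.values()):
        raise FitError("zero effective sample size; sampler did not move")

    mean_ = {n_: float(np.mean(flat[:, j])) for j, n_ in enumerate(_PARAM_NAMES)}
    sd_ = {n_: float(np.std(flat[:, j], ddof=1)) for j, n_ in enumerate(_PARAM_NAMES)}
    quants = {
        n_: {q: float(np.quantile(flat[:, j], q)) for q in _QUANTS}
        for j, n_ in enumerate(_PARAM_NAMES)
    }
    return PosteriorSummary(
        mean=mean_,
        sd=sd_,
        quantiles=quants,
        n_samples=flat.shape[0],
        seed=seed,
        acceptance_rate=acceptance,
        ess=ess,
        beta=beta,
        scale=scale,
        warnings=tuple(warnings),
    )


def paired_param_test(
    low_params: Sequence[float],
    high_params: Sequence[float],
) -> dict[str, float]:
    """Paired t test between matched LOW-set and HIGH-set parameter values.

    Returns ``{"t", "df", "p"}`` for the classical two-sided paired test
    with ``df = n - 1``.
    """
    low = np.asarray(low_params, dtype=float)
    high = np.asarray(high_params, dtype=float)
    if low.shape != high.shape:
        raise DomainError(f"length mismatch: {low.shape} vs {high.shape}")
    if low.size < 2:
        raise DomainError("need at least two matched pairs")
    if np.all(low == high):
        # zero-variance differences: no evidence against equality
        return {"t": 0.0, "df": float(low.size - 1), "p": 1.0}
    res = stats.ttest_rel(low, high)
    return {"t": float(res.statistic), "df": float(low.size - 1), "p": float(res.pvalue)}
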