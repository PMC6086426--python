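"""Candidate response-curve models and their maximum-likelihood fits.

Four mean functions describe how a community response can track percent
forest cover x:

* ``NULL`` — a flat mean m (no response);
* ``GLM``  — a straight line, intercept + slope * x (proportional change);
* ``LOG``  — a four-parameter logistic, d + a / (1 + exp((b - x) / c)):
  d is the lower diversity level, a the amount of loss (upper minus lower
  level), b the cover at which half the loss has occurred (the steepest
  point), and c the exponential rate of change;
* ``BELL`` — a Gaussian bump, a * exp(-(b * (x - d))**2) + c, the
  inverted-U response expected of habitat generalists: a is peak height
  above the baseline c, d the peak location, b the inverse width.

Counts (abundance) are modelled with Poisson errors on the identity scale;
mean alpha and gamma diversity with normal errors (residual SD sigma is a
free parameter).  Fitting maximizes the likelihood numerically with a
derivative-free simplex search and jittered multi-starts, which keeps the
kinked early iterations of the nonlinear means stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .community import ResponseSeries
from .errors import InputError

MODEL_NAMES = ("NULL", "GLM", "LOG", "BELL")
FAMILIES = ("poisson", "normal")

_PENALTY = 1e10
MEAN_FLOOR = 1e-9  # Poisson mean floor: LOG/BELL means may cross 0 mid-search
SIGMA_FLOOR = 1e-6

_PARAM_NAMES = {
    "NULL": ("m",),
    "GLM": ("intercept", "slope"),
    "LOG": ("a", "b", "c", "d"),
    "BELL": ("a", "b", "c", "d"),
}

#: K as reported in published AICc tables for this model family quartet
K_CONVENTIONAL = {"NULL": 2, "GLM": 3, "LOG": 4, "BELL": 4}


def n_params(model: str, family: str, k_mode: str = "conventional") -> int:
    """Parameter count K used in AICc.

    ``conventional`` mode uses the bookkeeping customary in published AICc
    tables for this model quartet
    (NULL=2, GLM=3, LOG=4, BELL=4 for both families); ``strict`` counts
    mean parameters plus one dispersion parameter for the normal family
    (and mean parameters only for Poisson, which has none).
    """
    if k_mode == "conventional":
        return K_CONVENTIONAL[model]
    if k_mode == "strict":
        k = len(_PARAM_NAMES[model])
        return k + 1 if family == "normal" else k
    raise InputError(f"unknown k_mode {k_mode!r}")


@dataclass
class ModelParams:
    """Named parameters of one fitted (or proposed) mean function."""

    model: str
    values: dict[str, float]
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise InputError(f"unknown model {self.model!r}")
        missing = set(_PARAM_NAMES[self.model]) - set(self.values)
        if missing:
            raise InputError(f"{self.model} params missing {sorted(missing)}")


def mean_null(x, params: ModelParams) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.full_like(x, params.values["m"])


def mean_linear(x, params: ModelParams) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return params.values["intercept"] + params.values["slope"] * x


def mean_logistic(x, params: ModelParams) -> np.ndarray:
    """Overflow-safe four-parameter logistic; saturates to its asymptotes."""
    x = np.asarray(x, dtype=float)
    v = params.values
    if v["c"] == 0:
        raise InputError("logistic rate parameter c must be nonzero")
    z = np.clip((v["b"] - x) / v["c"], -700.0, 700.0)
    return v["d"] + v["a"] / (1.0 + np.exp(z))


def mean_bell(x, params: ModelParams) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    v = params.values
    z = v["b"] * (x - v["d"])
    return v["a"] * np.exp(-(z * z)) + v["c"]


MEAN_FUNCTIONS = {
    "NULL": mean_null,
    "GLM": mean_linear,
    "LOG": mean_logistic,
    "BELL": mean_bell,
}


def model_mean(x, params: ModelParams) -> np.ndarray:
    return MEAN_FUNCTIONS[params.model](x, params)


def negloglik(series: ResponseSeries, model: str, params: ModelParams) -> float:
    """Negative log-likelihood of a parameterization on one series.

    Poisson: sum(mu_i - y_i log mu_i + log y_i!) with mu floored at
    ``MEAN_FLOOR``.  Normal: (n/2) log(2 pi sigma^2) + RSS / (2 sigma^2)
    with sigma floored at ``SIGMA_FLOOR``.  Any non-finite intermediate
    yields a large finite penalty so optimizers stay stable.
    """
    if params.model != model:
        raise InputError("params.model does not match the requested model")
    try:
        mu = model_mean(series.x, params)
    except (InputError, FloatingPointError):
        return _PENALTY
    if not np.all(np.isfinite(mu)):
        return _PENALTY
    y = series.y
    if series.family == "poisson":
        mu = np.maximum(mu, MEAN_FLOOR)
        nll = float(np.sum(mu - y * np.log(mu) + gammaln(y + 1.0)))
    else:
        sigma = max(params.sigma if params.sigma is not None else 0.0, SIGMA_FLOOR)
        rss = float(np.sum((y - mu) ** 2))
        nll = 0.5 * y.size * np.log(2.0 * np.pi * sigma * sigma) + rss / (2.0 * sigma * sigma)
    return nll if np.isfinite(nll) else _PENALTY


@dataclass
class FitConfig:
    """Controls of the multi-start simplex maximum-likelihood search."""

    n_restarts: int = 20
    seed: int = 0
    jitter: float = 0.3
    maxiter: int = 4000
    tol: float = 1e-8
    k_mode: str = "conventional"


@dataclass
class FitResult:
    model: str
    family: str
    params: ModelParams | None
    loglik: float
    K: int
    n: int
    converged: bool
    n_restarts_used: int = 0
    message: str = ""


def _pack(params: ModelParams, family: str) -> np.ndarray:
    theta = [params.values[k] for k in _PARAM_NAMES[params.model]]
    if family == "normal":
        theta.append(np.log(max(params.sigma, SIGMA_FLOOR)))
    return np.array(theta, dtype=float)


def _unpack(theta: np.ndarray, model: str, family: str) -> ModelParams:
    names = _PARAM_NAMES[model]
    values = dict(zip(names, map(float, theta[: len(names)])))
    sigma = float(np.exp(theta[len(names)])) if family == "normal" else None
    return ModelParams(model, values, sigma)


def _base_starts(series: ResponseSeries, model: str) -> list[dict[str, float]]:
    x, y = series.x, series.y
    ymin, ymax = float(y.min()), float(y.max())
    yr = ymax - ymin if ymax > ymin else max(abs(ymax), 1.0)
    xmid = float(np.median(x))
    xr = float(x.max() - x.min()) or 1.0
    if model == "NULL":
        return [{"m": float(y.mean())}]
    if model == "GLM":
        # OLS start serves both families
        slope, intercept = np.polyfit(x, y, 1)
        return [{"intercept": float(intercept), "slope": float(slope)}]
    if model == "LOG":
        rising = {"a": yr, "b": xmid, "c": 0.1 * xr, "d": ymin}
        falling = {"a": -yr, "b": xmid, "c": 0.1 * xr, "d": ymax}
        return [rising, falling]
    if model == "BELL":
        bump = {"a": yr, "b": 2.0 / xr, "c": ymin, "d": xmid}
        dip = {"a": -yr, "b": 2.0 / xr, "c": ymax, "d": xmid}
        return [bump, dip]
    raise InputError(f"unknown model {model!r}")


def fit(series: ResponseSeries, model: str, config: FitConfig | None = None) -> FitResult:
    """Fit one candidate model to a series by multi-start maximum likelihood.

    Restart 0 (and the mirrored restart for LOG/BELL) run from un-jittered
    heuristic starting values so closed-form-recoverable optima (NULL mean,
    OLS line) are reproduced to optimizer tolerance; remaining restarts
    jitter the starts with a seeded RNG, making the fit deterministic for a
    fixed ``config.seed``.
    """
    config = config or FitConfig()
    if model not in MODEL_NAMES:
        raise InputError(f"unknown model {model!r}")
    K = n_params(model, series.family, config.k_mode)
    if series.n < K + 2:
        return FitResult(
            model, series.family, None, -np.inf, K, series.n, False,
            message=f"too few observations (n={series.n} < K+2={K + 2})",
        )

    sigma0 = float(series.y.std()) or 1e-2
    bases = [
        ModelParams(model, vals, sigma0 if series.family == "normal" else None)
        for vals in _base_starts(series, model)
    ]
    rng = np.random.default_rng(config.seed)

    def objective(theta: np.ndarray) -> float:
        return negloglik(series, model, _unpack(theta, model, series.family))

    best = None
    used = 0
    for i in range(max(config.n_restarts, len(bases))):
        theta0 = _pack(bases[i % len(bases)], series.family)
        if i >= len(bases):
            scale = np.abs(theta0) + 0.1
            theta0 = theta0 + config.jitter * scale * rng.standard_normal(theta0.size)
        res = minimize(
            objective,
            theta0,
            method="Nelder-Mead",
            options={
                "xatol": config.tol,
                "fatol": config.tol,
                "maxiter": config.maxiter,
                "maxfev": config.maxiter,
            },
        )
        used += 1
        if np.isfinite(res.fun) and res.fun < _PENALTY / 2:
            if best is None or res.fun < best.fun:
                best = res

    if best is None:
        return FitResult(
            model, series.family, None, -np.inf, K, series.n, False,
            n_restarts_used=used, message="all restarts non-finite",
        )
    params = _unpack(best.x, model, series.family)
    return FitResult(
        model, series.family, params, -float(best.fun), K, series.n,
        converged=True, n_restarts_used=used, message=str(best.message),
    )


def fit_all(
    series: ResponseSeries,
    config: FitConfig | None = None,
    models: tuple[str, ...] = MODEL_NAMES,
) -> list[FitResult]:
    """Fit every candidate model to one series."""
    return [fit(series, m, config) for m in models]
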