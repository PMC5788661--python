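"""Pooled Gaussian maximum likelihood for the host-response models.

All replicate observations — across readouts, the dose sweep and the time
sweep — enter a single likelihood with i.i.d. Gaussian measurement error of
one shared standard deviation sigma:

    Y_i(t_j, D_k) = M(t_j, D_k; theta) + eta_ijk,   eta_ijk ~ N(0, sigma^2)

    l(theta, sigma) = -RSS(theta) / (2 sigma^2) - N_tot * log(sigma sqrt(2 pi))

sigma is profiled analytically (sigma_hat = sqrt(RSS/N_tot)), so the search
runs over the structural parameters only, in log space (all free parameters
are positive), with a multi-start Nelder-Mead simplex.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize

from .types import Dataset, ValidationError
from .models import ConfigurationError

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_TINY_RSS = 1e-300


class DegenerateFitWarning(UserWarning):
    """The residual sum of squares is (numerically) zero; the Gaussian
    likelihood is unbounded in sigma."""


class ConvergenceError(RuntimeError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, msg: str, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics


@dataclass
class FitConfig:
    """Controls for the multi-start simplex search.

    ``jitter_scale`` is the half-width of the log-uniform multiplicative
    jitter applied to the starting values (0.5 means factors in
    [exp(-0.5), exp(+0.5)], roughly +/-50%). The first start is unjittered
    unless ``jitter_first`` is set (useful for recovery experiments where the
    starting values coincide with the generating truth).
    """

    n_starts: int = 20
    init_strategy: str = "jittered"  # from_config | jittered | latin_hypercube
    jitter_scale: float = 0.5
    jitter_first: bool = False
    max_iter: int | None = None
    f_tol: float = 1e-9
    x_tol: float = 1e-6
    log_transform: bool = True
    n_polish: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValidationError("n_starts must be >= 1")
        if self.f_tol <= 0 or self.x_tol <= 0:
            raise ValidationError("tolerances must be > 0")
        if self.init_strategy not in ("from_config", "jittered", "latin_hypercube"):
            raise ValidationError(f"unknown init_strategy {self.init_strategy!r}")


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    model_label: str
    free_names: tuple[str, ...]
    theta: np.ndarray
    params: Any
    sigma_hat: float
    loglik: float
    n_params: int          # free structural parameters + 1 for sigma
    n_tot: int
    n_starts: int
    best_start: int
    converged: bool
    theta_spread: float
    identifiable: bool
    start_logliks: np.ndarray = field(repr=False, default=None)
    warnings: list[str] = field(default_factory=list)

    @property
    def theta_dict(self) -> dict[str, float]:
        return dict(zip(self.free_names, self.theta))

    def to_dict(self) -> dict:
        return {
            "model": self.model_label,
            "theta": {k: float(v) for k, v in self.theta_dict.items()},
            "sigma_hat": float(self.sigma_hat),
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "n_tot": int(self.n_tot),
            "n_starts": int(self.n_starts),
            "best_start": int(self.best_start),
            "converged": bool(self.converged),
            "theta_spread": float(self.theta_spread),
            "identifiable": bool(self.identifiable),
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# Likelihood pieces
# ---------------------------------------------------------------------------

def _model_cells(model, dataset: Dataset):
    arrays = dataset.arrays()
    extra = set(arrays) - set(model.readouts)
    if extra:
        raise ConfigurationError(
            f"dataset contains readout(s) {sorted(extra)} not covered by "
            f"model {model.label!r}")
    cells = {r: (d, t) for r, (d, t, _y) in arrays.items()}
    ys = {r: y for r, (_d, _t, y) in arrays.items()}
    return cells, ys


def residuals(model, theta, dataset: Dataset) -> np.ndarray:
    """Observed minus model mean, one entry per measurement in dataset order."""
    if theta is None:
        theta = model.init_theta()
    cells, ys = _model_cells(model, dataset)
    preds = model.predict_cells(theta, cells)
    out = np.empty(dataset.n_tot)
    for r, idx in dataset.row_order().items():
        out[idx] = ys[r] - preds[r]
    return out


def log_likelihood(model, theta, sigma: float, dataset: Dataset) -> float:
    """Pooled Gaussian log-likelihood at (theta, sigma)."""
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    res = residuals(model, theta, dataset)
    rss = float(res @ res)
    n = dataset.n_tot
    return -rss / (2.0 * sigma**2) - n * (math.log(sigma) + _LOG_SQRT_2PI)


def profile_sigma(model, theta, dataset: Dataset) -> float:
    """Analytic maximizer of the likelihood over sigma: sqrt(RSS / N_tot)."""
    res = residuals(model, theta, dataset)
    rss = float(res @ res)
    if rss == 0.0:
        warnings.warn("RSS is exactly 0: sigma_hat = 0 and the likelihood "
                      "is unbounded", DegenerateFitWarning, stacklevel=2)
        return 0.0
    return math.sqrt(rss / dataset.n_tot)


def _profiled_loglik(rss: float, n: int) -> float:
    rss = max(rss, _TINY_RSS)
    return -0.5 * n * (math.log(rss / n) + 1.0) - n * _LOG_SQRT_2PI


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _make_objective(model, dataset: Dataset, log_transform: bool):
    cells, ys = _model_cells(model, dataset)
    order = [(r, ys[r]) for r in ys]
    n = dataset.n_tot

    def nll(z: np.ndarray) -> float:
        theta = np.exp(z) if log_transform else z
        try:
            preds = model.predict_cells(theta, cells)
        except (ValidationError, FloatingPointError):
            return np.inf
        rss = 0.0
        for r, y in order:
            d = y - preds[r]
            rss += float(d @ d)
        if not np.isfinite(rss):
            return np.inf
        # concentrated (sigma-profiled) negative log-likelihood, up to the
        # additive constant n/2*(1 + log 2 pi)
        return 0.5 * n * math.log(max(rss, _TINY_RSS) / n)

    return nll


def _starting_points(z0: np.ndarray, config: FitConfig,
                     rng: np.random.Generator) -> np.ndarray:
    k, p = config.n_starts, len(z0)
    if config.init_strategy == "from_config":
        return np.tile(z0, (k, 1))
    if config.init_strategy == "latin_hypercube":
        # stratified log-uniform box of half-width jitter_scale around z0
        u = (rng.permuted(np.tile(np.arange(k), (p, 1)), axis=1).T
             + rng.uniform(size=(k, p))) / k
        pts = z0 + config.jitter_scale * (2.0 * u - 1.0)
    else:  # jittered
        pts = z0 + rng.uniform(-config.jitter_scale, config.jitter_scale,
                               size=(k, p))
    if not config.jitter_first:
        pts[0] = z0
    return pts


def fit_mle(model, dataset: Dataset, config: FitConfig | None = None) -> FitResult:
    """Multi-start Nelder-Mead maximum-likelihood fit with profiled sigma.

    Deterministic given ``config.seed``. The best start is polished by
    restarting the simplex at its own optimum (``n_polish`` times), which
    guards against premature simplex collapse.
    """
    config = config or FitConfig()
    theta0 = np.asarray(model.init_theta(), float)
    if config.log_transform and np.any(theta0 <= 0):
        raise ValidationError("log_transform requires strictly positive "
                              "starting values")
    z0 = np.log(theta0) if config.log_transform else theta0
    nll = _make_objective(model, dataset, config.log_transform)
    rng = np.random.default_rng(config.seed)
    starts = _starting_points(z0, config, rng)
    p = len(z0)
    maxiter = config.max_iter or 500 * p

    results = []
    for z_start in starts:
        res = optimize.minimize(nll, z_start, method="Nelder-Mead",
                                options={"maxiter": maxiter,
                                         "xatol": config.x_tol,
                                         "fatol": config.f_tol})
        results.append(res)

    fvals = np.array([r.fun for r in results])
    best_i = int(np.argmin(fvals))
    best = results[best_i]
    for _ in range(config.n_polish):
        polished = optimize.minimize(nll, best.x, method="Nelder-Mead",
                                     options={"maxiter": maxiter,
                                              "xatol": config.x_tol,
                                              "fatol": config.f_tol})
        if polished.fun <= best.fun:
            best = polished
    if not np.isfinite(best.fun):
        raise ConvergenceError(
            "no optimizer start reached a finite objective",
            diagnostics=[{"fun": float(r.fun), "nit": int(r.nit),
                          "message": r.message} for r in results])

    z_hat = best.x
    theta_hat = np.exp(z_hat) if config.log_transform else z_hat

    # multi-start agreement diagnostics: relative spread of near-best optima
    f_best = best.fun
    tol = 1e-4 * max(1.0, abs(f_best))
    near = [r.x for r in results if r.fun <= f_best + tol]
    if len(near) >= 2:
        zs = np.vstack(near)
        spread = float(np.max(zs.max(axis=0) - zs.min(axis=0)))
    else:
        spread = 0.0
    identifiable = spread < 0.05  # near-identical optima in log-parameter space

    fit_warnings = []
    if not identifiable:
        fit_warnings.append(
            f"multi-start optima disagree (log-scale spread {spread:.3g}); "
            "parameters may not be identifiable from this design")

    cells, ys = _model_cells(model, dataset)
    preds = model.predict_cells(theta_hat, cells)
    rss = sum(float((ys[r] - preds[r]) @ (ys[r] - preds[r])) for r in ys)
    n = dataset.n_tot
    y_scale = math.sqrt(sum(float(ys[r] @ ys[r]) for r in ys) / n)
    sigma_hat = math.sqrt(rss / n)
    if sigma_hat <= 1e-9 * max(1.0, y_scale):
        fit_warnings.append("RSS is numerically 0: degenerate fit, the "
                            "likelihood is unbounded in sigma")
    loglik = _profiled_loglik(rss, n)

    n_params = p + 1  # structural + sigma
    if n > 0 and n < n_params:
        fit_warnings.append(f"fewer observations ({n}) than parameters ({n_params})")

    start_lls = np.array([-f - 0.5 * n * (1.0 + 2.0 * _LOG_SQRT_2PI)
                          for f in fvals])
    return FitResult(
        model_label=model.label, free_names=tuple(model.free_names),
        theta=theta_hat, params=model.with_theta(theta_hat),
        sigma_hat=sigma_hat, loglik=loglik, n_params=n_params, n_tot=n,
        n_starts=config.n_starts, best_start=best_i,
        converged=bool(best.success or any(r.success for r in results)),
        theta_spread=spread, identifiable=identifiable,
        start_logliks=start_lls, warnings=fit_warnings,
    )


def fit_from(model, dataset: Dataset, theta_start: np.ndarray,
             config: FitConfig | None = None) -> FitResult:
    """Single-start fit warm-started at ``theta_start`` (natural scale).

    Used to fit a richer nested model from a null model's optimum, which
    guarantees the alternative's likelihood is at least the null's up to
    optimizer tolerance.
    """
    config = config or FitConfig()
    cfg = FitConfig(n_starts=1, init_strategy="from_config",
                    jitter_scale=0.0, max_iter=config.max_iter,
                    f_tol=config.f_tol, x_tol=config.x_tol,
                    log_transform=config.log_transform,
                    n_polish=config.n_polish, seed=config.seed)
    theta_start = np.asarray(theta_start, float)
    base_init = model.init_theta
    model.init_theta = lambda: theta_start
    try:
        return fit_mle(model, dataset, cfg)
    finally:
        model.init_theta = base_init
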