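"""Maximum-likelihood fitting of the candidate families and AICc scoring.

Each family is fitted to the species-level geometric means of one chemical.
The log-normal fit is the exact closed form (mean and n-denominator
standard deviation of ln x). The other families are maximized numerically
over unconstrained transforms (log of positive parameters) with a
derivative-free simplex search and a small multi-start schedule: the
moment-based initial point plus two starts with every positive parameter
perturbed by a factor drawn uniformly from [0.5, 1.5]. The Burr III start
is the fitted log-logistic embedded at shape2 = 1, so a converged Burr III
fit can never score below the log-logistic it nests.

Convergence failures are data, not exceptions: a failed fit is returned
with ``converged=False`` and excluded downstream, mirroring how SSD
practice handles the Burr III distribution's notorious instability on
small samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize

from .distributions import (
    FAMILIES,
    Family,
    N_PARAMS,
    ParamSet,
    log_density,
    quantile,
)
from .exceptions import (
    DomainError,
    EmptyEnsembleError,
    InsufficientDataError,
    UnavailableEstimateError,
)
from .ingest import ChemicalDataset

__all__ = ["FitResult", "HCEstimate", "aicc", "fit_mle", "fit_all", "hc"]

_PARAM_LO, _PARAM_HI = 1e-8, 1e8
_N_EXTRA_STARTS = 2  # perturbed restarts on top of the moment-based start


@dataclass(frozen=True)
class FitResult:
    """One family fitted to one dataset."""

    family: Family
    params: Optional[ParamSet]
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    diagnostics: Mapping = field(default_factory=dict)


@dataclass(frozen=True)
class HCEstimate:
    """A hazardous-concentration estimate: the p-quantile of one SSD."""

    p: float
    value: float
    method: str

    def __post_init__(self) -> None:
        if not (self.value > 0):
            raise DomainError("HC estimate must be positive")


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 < 1:
        raise DomainError(f"AICc undefined for n={n}, k={k} (n-k-1 < 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


# ---------------------------------------------------------------------------
# negative log-likelihoods on unconstrained parameter vectors


def _nll(theta: np.ndarray, family: Family, logx: np.ndarray, x: np.ndarray) -> float:
    """Negative log-likelihood; unconstrained theta (log of positive params).

    Works directly with the log-parameters so simplex excursions to extreme
    values degrade to an infinite NLL instead of overflowing.
    """
    theta = np.clip(np.asarray(theta, dtype=float), -200.0, 200.0)
    n = len(x)
    with np.errstate(over="ignore", invalid="ignore", under="ignore"):
        if family is Family.LLOGIS:
            mu, log_s = theta
            z = (logx - mu) / math.exp(log_s)
            ll = np.sum(-z - 2.0 * np.logaddexp(0.0, -z)) - n * log_s - np.sum(logx)
        elif family is Family.BURR3:
            log_b, log_c, log_lam = theta
            b, c = math.exp(log_b), math.exp(log_c)
            log_t = -b * (logx - log_lam)
            ll = (
                n * (log_b + log_c)
                + np.sum(log_t)
                - (c + 1.0) * np.sum(np.logaddexp(0.0, log_t))
                - np.sum(logx)
            )
        elif family is Family.WEIBULL:
            log_k, log_lam = theta
            kappa = math.exp(log_k)
            r = logx - log_lam
            ll = n * (log_k - log_lam) + np.sum((kappa - 1.0) * r - np.exp(kappa * r))
        elif family is Family.GAMMA:
            log_a, log_th = theta
            alpha = math.exp(log_a)
            from scipy.special import gammaln

            ll = (
                -n * (gammaln(alpha) + alpha * log_th)
                + (alpha - 1.0) * np.sum(logx)
                - np.sum(x) * math.exp(-log_th)
            )
        else:  # pragma: no cover
            raise DomainError(f"no numeric NLL for family {family}")
    if not np.isfinite(ll):
        return math.inf
    return float(-ll)


def _to_paramset(family: Family, theta: np.ndarray) -> ParamSet:
    if family is Family.LLOGIS:
        return ParamSet(family, (float(theta[0]), float(math.exp(theta[1]))))
    return ParamSet(family, tuple(float(v) for v in np.exp(theta)))


def _initial_theta(family: Family, logx: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Moment-based starting point on the unconstrained scale."""
    m, sd = float(np.mean(logx)), float(np.std(logx))
    sd = max(sd, 1e-4)  # guard nearly-degenerate samples
    if family is Family.LLOGIS:
        # logistic on ln x: sd = s * pi / sqrt(3)
        return np.array([m, math.log(sd * math.sqrt(3.0) / math.pi)])
    if family is Family.WEIBULL:
        # Var(ln X) = pi^2 / (6 kappa^2); E(ln X) = ln lam - gamma/kappa
        kappa0 = math.pi / (sd * math.sqrt(6.0))
        lam0 = math.exp(m + 0.5772156649 / kappa0)
        return np.log([kappa0, lam0])
    if family is Family.GAMMA:
        mean, var = float(np.mean(x)), float(np.var(x))
        var = max(var, 1e-12 * mean * mean + 1e-300)
        alpha0 = max(mean * mean / var, 1e-3)
        theta0 = max(var / mean, 1e-300)
        return np.log([alpha0, theta0])
    raise DomainError(f"no moment initialization for family {family}")


def _fit_lnorm(values: np.ndarray) -> tuple[ParamSet, float]:
    """Closed-form log-normal MLE (variance with n denominator)."""
    logx = np.log(values)
    mu = float(np.mean(logx))
    sigma = float(np.sqrt(np.mean((logx - mu) ** 2)))
    sigma = max(sigma, 1e-12)  # degenerate sample: all values equal
    ps = ParamSet(Family.LNORM, (mu, sigma))
    return ps, float(np.sum(log_density(ps, values)))


def _params_in_bounds(ps: ParamSet) -> bool:
    # log-location parameters are unconstrained reals; positive parameters
    # must sit well inside (0, inf) for the fit to count as converged
    from .distributions import PARAM_NAMES

    for name, v in zip(PARAM_NAMES[ps.family], ps.params):
        if name in ("meanlog", "locationlog"):
            if not abs(v) <= math.log(_PARAM_HI):
                return False
        elif not (_PARAM_LO <= v <= _PARAM_HI):
            return False
    return True


def _quantiles_usable(ps: ParamSet) -> bool:
    """A fit whose extreme quantiles under- or overflow cannot yield HC
    estimates and is treated as a convergence failure."""
    try:
        lo, hi = quantile(ps, 1e-3), quantile(ps, 1.0 - 1e-3)
    except (DomainError, FloatingPointError, OverflowError):
        return False
    return 0.0 < lo <= hi < math.inf


def fit_mle(
    dataset: ChemicalDataset,
    family: Family,
    init: Optional[ParamSet] = None,
    optimizer_config: Optional[Mapping] = None,
) -> FitResult:
    """Fit one family to a species-level dataset by maximum likelihood.

    Raises :class:`InsufficientDataError` when n < k + 2 (the AICc
    denominator requirement). Numerical failure to converge is reported via
    ``converged=False``, never as an exception.
    """
    cfg = dict(optimizer_config or {})
    family = Family(family)
    k = N_PARAMS[family]
    n = dataset.n_species
    if n < k + 2:
        raise InsufficientDataError(
            f"{family.value} needs at least {k + 2} species, got {n}"
        )
    values = dataset.values

    if family is Family.LNORM:
        ps, loglik = _fit_lnorm(values)
        return FitResult(
            family=family,
            params=ps,
            loglik=loglik,
            k=k,
            n=n,
            aicc=aicc(loglik, k, n),
            converged=True,
            diagnostics={"method": "closed_form"},
        )

    logx = np.log(values)
    rng = np.random.default_rng(cfg.get("seed", 0))
    maxiter = cfg.get("maxiter", 600)

    starts: list[np.ndarray] = []
    if init is not None:
        if init.family is not family:
            raise DomainError("init parameter set is for a different family")
        if family is Family.LLOGIS:
            starts.append(np.array([init.params[0], math.log(init.params[1])]))
        else:
            starts.append(np.log(np.asarray(init.params)))
    if family is Family.BURR3:
        # start at the fitted log-logistic embedded as burr3 with shape2 = 1
        ll_fit = fit_mle(dataset, Family.LLOGIS, optimizer_config=cfg)
        if ll_fit.converged and ll_fit.params is not None:
            mu, s = ll_fit.params.params
            starts.append(np.log([1.0 / s, 1.0, math.exp(mu)]))
        else:
            m, sd = float(np.mean(logx)), max(float(np.std(logx)), 1e-4)
            starts.append(np.log([math.pi / (sd * math.sqrt(3.0)), 1.0, math.exp(m)]))
    else:
        starts.append(_initial_theta(family, logx, values))
    base = starts[-1]
    for _ in range(_N_EXTRA_STARTS):
        starts.append(base + np.log(rng.uniform(0.5, 1.5, size=k)))

    best: Optional[optimize.OptimizeResult] = None
    tried = 0
    for theta0 in starts:
        if not np.isfinite(_nll(theta0, family, logx, values)):
            continue
        res = optimize.minimize(
            _nll,
            theta0,
            args=(family, logx, values),
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-10},
        )
        tried += 1
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res

    if best is None:
        return FitResult(
            family=family,
            params=None,
            loglik=-math.inf,
            k=k,
            n=n,
            aicc=math.inf,
            converged=False,
            diagnostics={"message": "non-finite likelihood at every start"},
        )
    try:
        ps = _to_paramset(family, best.x)
    except DomainError:
        ps = None
    loglik = -float(best.fun)
    converged = bool(
        best.success
        and ps is not None
        and math.isfinite(loglik)
        and _params_in_bounds(ps)
        and _quantiles_usable(ps)
    )
    return FitResult(
        family=family,
        params=ps,
        loglik=loglik,
        k=k,
        n=n,
        aicc=aicc(loglik, k, n) if converged else math.inf,
        converged=converged,
        diagnostics={
            "iterations": int(best.nit),
            "message": str(best.message),
            "starts_tried": tried,
        },
    )


def fit_all(
    dataset: ChemicalDataset,
    families: Sequence[Family] = FAMILIES,
    optimizer_config: Optional[Mapping] = None,
) -> list[FitResult]:
    """Fit every requested family; failures are flagged, never dropped.

    A family that cannot be fitted for lack of data (n < k + 2) yields a
    flagged, non-converged result. Raises :class:`EmptyEnsembleError` only
    when no family at all converged.
    """
    if not families:
        raise DomainError("families must be nonempty")
    results: list[FitResult] = []
    for family in families:
        family = Family(family)
        try:
            results.append(fit_mle(dataset, family, optimizer_config=optimizer_config))
        except InsufficientDataError as exc:
            results.append(
                FitResult(
                    family=family,
                    params=None,
                    loglik=-math.inf,
                    k=N_PARAMS[family],
                    n=dataset.n_species,
                    aicc=math.inf,
                    converged=False,
                    diagnostics={"message": f"insufficient data: {exc}"},
                )
            )
    if not any(r.converged for r in results):
        raise EmptyEnsembleError(
            f"no family converged on chemical {dataset.chemical_id!r}"
        )
    return results


def hc(fit: FitResult, p: float = 0.05) -> HCEstimate:
    """Hazardous concentration HC_p from one converged fit."""
    if not fit.converged or fit.params is None:
        raise UnavailableEstimateError(
            f"{fit.family.value} fit did not converge; HC unavailable"
        )
    return HCEstimate(p=p, value=quantile(fit.params, p), method=fit.family.value)
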