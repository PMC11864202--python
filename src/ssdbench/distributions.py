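"""The five candidate SSD families on the positive half-line.

A species sensitivity distribution (SSD) models interspecies variation in
sensitivity to a chemical; the hazardous concentration HC_p is its
p-quantile. The candidate set comprises the log-normal, log-logistic,
Burr type III, Weibull, and gamma distributions. Every function here is a
closed form (gamma quantile via the regularized incomplete gamma inverse),
so the layer is fast enough to sit inside a likelihood loop.

Parameterizations
-----------------
lnorm    (meanlog mu in R, sdlog sigma > 0):
             F(x) = Phi((ln x - mu) / sigma)
llogis   (locationlog mu in R, scalelog s > 0) -- a logistic distribution
         for ln x, so the log-logistic on the original scale:
             F(x) = 1 / (1 + exp(-(ln x - mu)/s))
burr3    (shape1 b > 0, shape2 c > 0, scale lam > 0):
             F(x) = (1 + (x/lam)^(-b))^(-c)
         Burr III conventions vary between packages; this three-parameter
         form contains the log-logistic as the special case c = 1 with
         mu = ln(lam), s = 1/b. Check parameter order when comparing
         against other software.
weibull  (shape kappa > 0, scale lam > 0):
             F(x) = 1 - exp(-(x/lam)^kappa)
gamma    (shape alpha > 0, scale theta > 0; scale, not rate):
             F(x) = P(alpha, x/theta)   (regularized lower inc. gamma)

Support is the open interval (0, inf); zero or negative concentrations are
rejected as domain errors (they must be filtered upstream).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import special

from .exceptions import DomainError

__all__ = [
    "Family",
    "ParamSet",
    "FAMILIES",
    "N_PARAMS",
    "PARAM_NAMES",
    "cdf",
    "quantile",
    "log_density",
    "gamma_rate_to_scale",
    "gamma_scale_to_rate",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class Family(str, enum.Enum):
    """Identifier of one candidate family."""

    LNORM = "lnorm"
    LLOGIS = "llogis"
    BURR3 = "burr3"
    WEIBULL = "weibull"
    GAMMA = "gamma"


FAMILIES: tuple[Family, ...] = (
    Family.LNORM,
    Family.LLOGIS,
    Family.BURR3,
    Family.WEIBULL,
    Family.GAMMA,
)

#: number of free parameters k per family (Burr III is the only 3-parameter one)
N_PARAMS: Mapping[Family, int] = {
    Family.LNORM: 2,
    Family.LLOGIS: 2,
    Family.BURR3: 3,
    Family.WEIBULL: 2,
    Family.GAMMA: 2,
}

PARAM_NAMES: Mapping[Family, tuple[str, ...]] = {
    Family.LNORM: ("meanlog", "sdlog"),
    Family.LLOGIS: ("locationlog", "scalelog"),
    Family.BURR3: ("shape1", "shape2", "scale"),
    Family.WEIBULL: ("shape", "scale"),
    Family.GAMMA: ("shape", "scale"),
}

# indices of parameters that must be strictly positive
_POSITIVE: Mapping[Family, tuple[int, ...]] = {
    Family.LNORM: (1,),
    Family.LLOGIS: (1,),
    Family.BURR3: (0, 1, 2),
    Family.WEIBULL: (0, 1),
    Family.GAMMA: (0, 1),
}


@dataclass(frozen=True)
class ParamSet:
    """A family together with a fully specified parameter vector.

    ``params`` is ordered as in :data:`PARAM_NAMES`. Positivity constraints
    are checked on construction.
    """

    family: Family
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        family = Family(self.family)
        object.__setattr__(self, "family", family)
        params = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", params)
        k = N_PARAMS[family]
        if len(params) != k:
            raise DomainError(
                f"{family.value} takes {k} parameters, got {len(params)}"
            )
        if not all(math.isfinite(v) for v in params):
            raise DomainError(f"non-finite parameter in {params}")
        for i in _POSITIVE[family]:
            if params[i] <= 0:
                name = PARAM_NAMES[family][i]
                raise DomainError(
                    f"{family.value} parameter {name} must be > 0, got {params[i]}"
                )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES[self.family], self.params))

    def to_json_dict(self) -> dict:
        return {"family": self.family.value, "params": self.as_dict()}

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "ParamSet":
        family = Family(d["family"])
        params = tuple(d["params"][name] for name in PARAM_NAMES[family])
        return cls(family, params)


def _check_positive(x: np.ndarray, what: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0) or not np.all(np.isfinite(x)):
        raise DomainError(f"{what} must be positive and finite")
    return x


def cdf(ps: ParamSet, x):
    """Cumulative distribution function F(x) on (0, inf)."""
    xa = _check_positive(x)
    f = ps.family
    if f is Family.LNORM:
        mu, sigma = ps.params
        out = special.ndtr((np.log(xa) - mu) / sigma)
    elif f is Family.LLOGIS:
        mu, s = ps.params
        out = special.expit((np.log(xa) - mu) / s)
    elif f is Family.BURR3:
        b, c, lam = ps.params
        # (1 + (x/lam)^(-b))^(-c), computed in logs for stability
        log_t = -b * (np.log(xa) - math.log(lam))
        out = np.exp(-c * np.logaddexp(0.0, log_t))
    elif f is Family.WEIBULL:
        kappa, lam = ps.params
        out = -np.expm1(-((xa / lam) ** kappa))
    elif f is Family.GAMMA:
        alpha, theta = ps.params
        out = special.gammainc(alpha, xa / theta)
    else:  # pragma: no cover
        raise DomainError(f"unknown family {f}")
    return out if np.ndim(x) else float(out)


def quantile(ps: ParamSet, p):
    """Quantile function Q(p) = F^{-1}(p), the hazardous concentration HC_p."""
    pa = np.asarray(p, dtype=float)
    if np.any((pa <= 0.0) | (pa >= 1.0)) or not np.all(np.isfinite(pa)):
        raise DomainError("p must lie strictly inside (0, 1)")
    f = ps.family
    if f is Family.LNORM:
        mu, sigma = ps.params
        out = np.exp(mu + sigma * special.ndtri(pa))
    elif f is Family.LLOGIS:
        mu, s = ps.params
        out = np.exp(mu + s * special.logit(pa))
    elif f is Family.BURR3:
        b, c, lam = ps.params
        # Q = lam * (p^(-1/c) - 1)^(-1/b), in logs: with t = -ln(p)/c > 0,
        # ln(p^(-1/c) - 1) = ln(expm1(t)) = t + log1p(-exp(-t))
        t = -np.log(pa) / c
        log_expm1 = t + np.log1p(-np.exp(-t))
        out = np.exp(math.log(lam) - log_expm1 / b)
    elif f is Family.WEIBULL:
        kappa, lam = ps.params
        out = lam * np.power(-np.log1p(-pa), 1.0 / kappa)
    elif f is Family.GAMMA:
        alpha, theta = ps.params
        out = theta * special.gammaincinv(alpha, pa)
    else:  # pragma: no cover
        raise DomainError(f"unknown family {f}")
    return out if np.ndim(p) else float(out)


def log_density(ps: ParamSet, x):
    """Natural log of the density f(x) = dF/dx on (0, inf)."""
    xa = _check_positive(x)
    logx = np.log(xa)
    f = ps.family
    if f is Family.LNORM:
        mu, sigma = ps.params
        z = (logx - mu) / sigma
        out = -logx - math.log(sigma) - _LOG_SQRT_2PI - 0.5 * z * z
    elif f is Family.LLOGIS:
        mu, s = ps.params
        z = (logx - mu) / s
        # logistic density in z, transformed by dz/dx = 1/(s x)
        out = -z - 2.0 * np.logaddexp(0.0, -z) - math.log(s) - logx
    elif f is Family.BURR3:
        b, c, lam = ps.params
        log_t = -b * (logx - math.log(lam))
        out = (
            math.log(b)
            + math.log(c)
            + log_t
            - (c + 1.0) * np.logaddexp(0.0, log_t)
            - logx
        )
    elif f is Family.WEIBULL:
        kappa, lam = ps.params
        r = logx - math.log(lam)
        out = math.log(kappa) - math.log(lam) + (kappa - 1.0) * r - np.exp(kappa * r)
    elif f is Family.GAMMA:
        alpha, theta = ps.params
        out = (
            -special.gammaln(alpha)
            - alpha * math.log(theta)
            + (alpha - 1.0) * logx
            - xa / theta
        )
    else:  # pragma: no cover
        raise DomainError(f"unknown family {f}")
    return out if np.ndim(x) else float(out)


def gamma_rate_to_scale(shape: float, rate: float) -> ParamSet:
    """Build a gamma ParamSet from the shape/rate convention."""
    if rate <= 0:
        raise DomainError("rate must be > 0")
    return ParamSet(Family.GAMMA, (shape, 1.0 / rate))


def gamma_scale_to_rate(ps: ParamSet) -> tuple[float, float]:
    """Return (shape, rate) for a gamma ParamSet in shape/scale form."""
    if ps.family is not Family.GAMMA:
        raise DomainError("not a gamma parameter set")
    alpha, theta = ps.params
    return alpha, 1.0 / theta
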