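"""AICc-based Akaike weights and model-averaged hazardous concentrations.

The weight of model i in a candidate set of K fitted distributions is

    w_i = exp(-dAICc_i / 2) / sum_k exp(-dAICc_k / 2),

with dAICc_i = AICc_i - min_k AICc_k. Weights are computed after
subtracting the minimum AICc, so large spreads cannot underflow the
numerator of the best model. The model-averaged HC_p combines the
per-family quantiles; three combination rules are provided:

arithmetic      sum_i w_i * HC_i              (the default; a literal
                "weighted average of the estimated HC values")
geometric       exp(sum_i w_i * ln HC_i)
distributional  the p-quantile of the weighted mixture CDF, i.e. the root
                of sum_i w_i F_i(x) = p

All three lie within [min_i HC_i, max_i HC_i]: the arithmetic and
geometric rules are weighted means, and the mixture CDF at min_i HC_i is
at most p and at max_i HC_i at least p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .distributions import cdf
from .exceptions import DomainError, EmptyEnsembleError, NumericError
from .fitting import FitResult, HCEstimate, hc

__all__ = [
    "FitEnsemble",
    "akaike_weights",
    "build_ensemble",
    "model_averaged_hc",
    "AVERAGING_METHODS",
]

AVERAGING_METHODS = ("arithmetic", "geometric", "distributional")

MODEL_AVERAGE_LABEL = "model_average"


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Akaike weights from a vector of AICc scores (all finite)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise DomainError("aicc_values must be nonempty")
    if not np.all(np.isfinite(a)):
        raise DomainError(
            "non-finite AICc in candidate set; exclude failed fits first"
        )
    delta = a - np.min(a)
    w = np.exp(-0.5 * delta)
    return w / np.sum(w)


@dataclass(frozen=True)
class FitEnsemble:
    """The converged candidate set with its dAICc values and Akaike weights."""

    fits: tuple[FitResult, ...]
    delta_aicc: tuple[float, ...]
    weights: tuple[float, ...]

    @property
    def k_models(self) -> int:
        return len(self.fits)


def build_ensemble(
    fits: Sequence[FitResult], exclusion: str = "drop_failed"
) -> FitEnsemble:
    """Drop failed fits and compute dAICc and weights over the survivors."""
    if exclusion != "drop_failed":
        raise DomainError(f"unknown exclusion policy {exclusion!r}")
    survivors = tuple(
        f for f in fits if f.converged and np.isfinite(f.aicc) and f.params is not None
    )
    if not survivors:
        raise EmptyEnsembleError("no converged fit to build an ensemble from")
    aiccs = np.array([f.aicc for f in survivors])
    weights = akaike_weights(aiccs)
    delta = aiccs - np.min(aiccs)
    return FitEnsemble(
        fits=survivors,
        delta_aicc=tuple(float(d) for d in delta),
        weights=tuple(float(w) for w in weights),
    )


def model_averaged_hc(
    ensemble: FitEnsemble, p: float = 0.05, method: str = "arithmetic"
) -> HCEstimate:
    """Model-averaged hazardous concentration HC_p over the ensemble."""
    if method not in AVERAGING_METHODS:
        raise DomainError(
            f"unknown averaging method {method!r}; allowed: {AVERAGING_METHODS}"
        )
    if not (0.0 < p < 1.0):
        raise DomainError("p must lie in (0, 1)")
    w = np.asarray(ensemble.weights)
    hcs = np.array([hc(f, p).value for f in ensemble.fits])
    if method == "arithmetic":
        value = float(np.sum(w * hcs))
    elif method == "geometric":
        value = float(np.exp(np.sum(w * np.log(hcs))))
    else:
        value = _mixture_quantile(ensemble, p, hcs)
    # clip tiny float excursions outside the sandwich bound
    value = float(min(max(value, hcs.min()), hcs.max()))
    return HCEstimate(p=p, value=value, method=MODEL_AVERAGE_LABEL)


def _mixture_quantile(ensemble: FitEnsemble, p: float, hcs: np.ndarray) -> float:
    """Root of sum_i w_i F_i(x) = p by bracketed root-finding."""
    w = np.asarray(ensemble.weights)
    params = [f.params for f in ensemble.fits]

    def g(x: float) -> float:
        return float(sum(wi * cdf(ps, x) for wi, ps in zip(w, params))) - p

    lo, hi = float(hcs.min()), float(hcs.max())
    if lo == hi:
        return lo
    # the root lies in [min HC, max HC] by monotonicity, but guard against
    # boundary rounding with a widen-and-retry schedule
    for widen in (1.0, 10.0, 100.0):
        a, b = lo / widen, hi * widen
        ga, gb = g(a), g(b)
        if ga <= 0.0 <= gb:
            return float(optimize.brentq(g, a, b, xtol=1e-12, rtol=1e-12))
    raise NumericError("mixture quantile root could not be bracketed")
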