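"""The subsampling benchmark: how well do SSDs fitted to few species
recover the nonparametric HC of the full dataset?

For each chemical with a large complete dataset, small datasets of 5, 10,
or 15 species are drawn without replacement, constrained to span at least
three taxonomic groups (rejection sampling, so the draw is uniform over
constraint-satisfying subsets). Each subsample is fitted with all five
candidate families; each converged family and the AICc-weighted model
average yield an HC estimate, and the deviation

    log10(HC_estimate) - log10(HC_reference)

is recorded. Failed fits are excluded from that approach's percentile
summary (the denominator shrinks); the model average is taken over the
surviving families of the same subsample, so all arms see identical data.

Bimodality of a complete dataset is screened with the bimodality
coefficient BC = (g1^2 + 1) / (g2 + 3(n-1)^2 / ((n-2)(n-3))) computed on
log10-transformed species geometric means, with g1 and g2 the
bias-corrected sample skewness and excess kurtosis. A large normal sample
gives BC -> 1/3 and a large uniform sample BC -> 1/1.8 ~ 0.5556; values
strictly above 0.555 flag bi- or multimodality. Bimodal and unimodal
chemicals are compared per approach with Welch's two-sample t-test and
Holm's step-down adjustment across the six approaches.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .averaging import MODEL_AVERAGE_LABEL, build_ensemble, model_averaged_hc
from .distributions import FAMILIES, Family
from .exceptions import (
    ConfigError,
    DomainError,
    EmptyEnsembleError,
    InsufficientDataError,
    NumericError,
)
from .fitting import fit_all, hc
from .ingest import ChemicalDataset, empirical_quantile, reference_hc

logger = logging.getLogger(__name__)

__all__ = [
    "SubsampleSpec",
    "DeviationRecord",
    "DeviationSummary",
    "BimodalityResult",
    "APPROACHES",
    "subsample",
    "run_benchmark",
    "summarize_deviations",
    "aggregate_across_chemicals",
    "bimodality_coefficient",
    "compare_groups",
]

BIMODALITY_THRESHOLD = 0.555
_MAX_REDRAWS = 10_000

#: the six estimation approaches compared by the benchmark
APPROACHES: tuple[str, ...] = tuple(f.value for f in FAMILIES) + (MODEL_AVERAGE_LABEL,)


@dataclass(frozen=True)
class SubsampleSpec:
    """How to subsample one chemical: size, iteration count, group constraint."""

    size: int = 15
    iterations: int = 1000
    min_groups: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < self.min_groups:
            raise ConfigError("size must be >= min_groups")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")


@dataclass(frozen=True)
class DeviationRecord:
    """One (iteration, approach) outcome: a log10 deviation or an exclusion."""

    chemical_id: str
    iteration: int
    approach: str
    p: float
    deviation: float
    excluded: bool


@dataclass(frozen=True)
class DeviationSummary:
    """Per-(chemical, approach) percentile summary of the deviations."""

    chemical_id: str
    approach: str
    q025: float
    q50: float
    q975: float
    n_used: int


@dataclass(frozen=True)
class BimodalityResult:
    """Bimodality screen of one complete dataset."""

    chemical_id: str
    n: int
    skewness: float
    excess_kurtosis: float
    bc: float
    bimodal: bool


def _chem_stream(seed: int, chemical_id: str, iteration: int) -> np.random.Generator:
    """Independent substream per (chemical, iteration), split by counters."""
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(chemical_id.encode("utf-8")), iteration]
    )


def subsample(
    dataset: ChemicalDataset,
    spec: SubsampleSpec,
    rng: np.random.Generator,
) -> ChemicalDataset:
    """Draw `spec.size` species without replacement, uniformly among subsets
    spanning at least `spec.min_groups` taxonomic groups (rejection)."""
    if dataset.n_groups < spec.min_groups:
        raise ConfigError(
            f"chemical {dataset.chemical_id!r} has only {dataset.n_groups} "
            f"taxonomic groups; constraint of {spec.min_groups} unsatisfiable"
        )
    if dataset.n_species < spec.size:
        raise InsufficientDataError(
            f"cannot draw {spec.size} species from {dataset.n_species}"
        )
    groups = dataset.groups
    for _ in range(_MAX_REDRAWS):
        idx = rng.choice(dataset.n_species, size=spec.size, replace=False)
        if len({groups[i] for i in idx}) >= spec.min_groups:
            return dataset.subset(sorted(int(i) for i in idx))
    raise NumericError(
        f"subsample constraint not met in {_MAX_REDRAWS} redraws "
        f"for chemical {dataset.chemical_id!r}"
    )


def run_benchmark(
    dataset: ChemicalDataset,
    spec: SubsampleSpec,
    p: float = 0.05,
    families: Sequence[Family] = FAMILIES,
    averaging_method: str = "arithmetic",
    quantile_method: str = "linear_type7",
) -> list[DeviationRecord]:
    """Run the full subsampling experiment for one chemical.

    Returns iterations x (len(families) + 1) records; an approach that
    fails in an iteration is recorded with ``excluded=True``.
    """
    ref = reference_hc(dataset, p=p, quantile_method=quantile_method)
    log_ref = np.log10(ref)
    approaches = [Family(f).value for f in families] + [MODEL_AVERAGE_LABEL]
    records: list[DeviationRecord] = []
    n_failed_iterations = 0
    for it in range(spec.iterations):
        rng = _chem_stream(spec.seed, dataset.chemical_id, it)
        sub = subsample(dataset, spec, rng)
        try:
            fits = fit_all(sub, families=families)
        except EmptyEnsembleError:
            n_failed_iterations += 1
            logger.warning(
                "chemical %s iteration %d: no family converged; all approaches excluded",
                dataset.chemical_id,
                it,
            )
            records.extend(
                DeviationRecord(dataset.chemical_id, it, a, p, float("nan"), True)
                for a in approaches
            )
            continue
        for fit in fits:
            if fit.converged:
                dev = float(np.log10(hc(fit, p).value) - log_ref)
                records.append(
                    DeviationRecord(dataset.chemical_id, it, fit.family.value, p, dev, False)
                )
            else:
                logger.debug(
                    "chemical %s iteration %d: %s fit excluded (%s)",
                    dataset.chemical_id,
                    it,
                    fit.family.value,
                    fit.diagnostics.get("message", ""),
                )
                records.append(
                    DeviationRecord(
                        dataset.chemical_id, it, fit.family.value, p, float("nan"), True
                    )
                )
        ensemble = build_ensemble(fits)
        ma = model_averaged_hc(ensemble, p=p, method=averaging_method)
        records.append(
            DeviationRecord(
                dataset.chemical_id,
                it,
                MODEL_AVERAGE_LABEL,
                p,
                float(np.log10(ma.value) - log_ref),
                False,
            )
        )
    if n_failed_iterations:
        logger.info(
            "chemical %s: %d/%d iterations had no converged fit",
            dataset.chemical_id,
            n_failed_iterations,
            spec.iterations,
        )
    return records


def records_to_frame(records: Sequence[DeviationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chemical_id": r.chemical_id,
                "iteration": r.iteration,
                "approach": r.approach,
                "p": r.p,
                "deviation": r.deviation,
                "excluded": r.excluded,
            }
            for r in records
        ]
    )


def summarize_deviations(
    records: Sequence[DeviationRecord],
    quantile_method: str = "linear_type7",
) -> list[DeviationSummary]:
    """2.5 / 50 / 97.5 percentile of the non-excluded deviations per
    (chemical, approach), same quantile convention as the reference HC."""
    if not records:
        raise DomainError("records must be nonempty")
    df = records_to_frame(records)
    summaries: list[DeviationSummary] = []
    for (cid, approach), sub in df.groupby(["chemical_id", "approach"], sort=False):
        devs = sub.loc[~sub["excluded"], "deviation"].to_numpy()
        if devs.size == 0:
            summaries.append(
                DeviationSummary(cid, approach, float("nan"), float("nan"), float("nan"), 0)
            )
            continue
        q = [empirical_quantile(devs, pr, quantile_method) for pr in (0.025, 0.5, 0.975)]
        summaries.append(DeviationSummary(cid, approach, q[0], q[1], q[2], int(devs.size)))
    return summaries


def summaries_to_frame(summaries: Sequence[DeviationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chemical_id": s.chemical_id,
                "approach": s.approach,
                "q025": s.q025,
                "q50": s.q50,
                "q975": s.q975,
                "n_used": s.n_used,
            }
            for s in summaries
        ]
    )


def aggregate_across_chemicals(
    summaries: Sequence[DeviationSummary],
) -> pd.DataFrame:
    """Cross-chemical mean / min / max of each percentile column per approach."""
    if not summaries:
        raise DomainError("summaries must be nonempty")
    df = summaries_to_frame(summaries)
    agg = df.groupby("approach", sort=False)[["q025", "q50", "q975"]].agg(
        ["mean", "min", "max"]
    )
    agg.columns = [f"{col}_{stat}" for col, stat in agg.columns]
    return agg.reset_index()


def bimodality_coefficient(
    values: Sequence[float],
    log_transform: bool = True,
    chemical_id: str = "",
) -> BimodalityResult:
    """Bimodality coefficient of a sample (log10 scale by default).

    BC = (g1^2 + 1) / (g2 + 3(n-1)^2 / ((n-2)(n-3))), with bias-corrected
    skewness g1 and excess kurtosis g2. BC strictly above 0.555 (the
    asymptotic value for a uniform distribution) flags bimodality.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("bimodality coefficient needs n >= 4")
    if log_transform:
        if np.any(x <= 0):
            raise DomainError("values must be positive for log10 transform")
        x = np.log10(x)
    if np.ptp(x) == 0.0 or np.var(x) == 0.0:
        raise NumericError("zero variance: bimodality coefficient undefined")
    n = x.size
    g1 = float(stats.skew(x, bias=False))
    g2 = float(stats.kurtosis(x, fisher=True, bias=False))
    correction = 3.0 * (n - 1.0) ** 2 / ((n - 2.0) * (n - 3.0))
    bc = (g1 * g1 + 1.0) / (g2 + correction)
    return BimodalityResult(
        chemical_id=chemical_id,
        n=n,
        skewness=g1,
        excess_kurtosis=g2,
        bc=float(bc),
        bimodal=bool(bc > BIMODALITY_THRESHOLD),
    )


def compare_groups(
    summaries: Sequence[DeviationSummary],
    flags: Sequence[BimodalityResult],
    percentile: str = "q975",
) -> pd.DataFrame:
    """Welch's t-test of bimodal vs unimodal chemicals, per approach, on one
    percentile column, with Holm adjustment across the approaches."""
    if percentile not in ("q025", "q50", "q975"):
        raise DomainError("percentile must be one of q025, q50, q975")
    df = summaries_to_frame(summaries)
    flag_map = {f.chemical_id: f.bimodal for f in flags}
    df["bimodal"] = df["chemical_id"].map(flag_map)
    if df["bimodal"].isna().any():
        missing = sorted(df.loc[df["bimodal"].isna(), "chemical_id"].unique())
        raise DomainError(f"no bimodality flag for chemicals {missing}")
    rows = []
    for approach, sub in df.groupby("approach", sort=False):
        a = sub.loc[sub["bimodal"], percentile].dropna().to_numpy()
        b = sub.loc[~sub["bimodal"], percentile].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise InsufficientDataError(
                f"group comparison for {approach!r} needs >= 2 chemicals per group "
                f"(bimodal: {len(a)}, unimodal: {len(b)})"
            )
        if np.var(a) == 0.0 and np.var(b) == 0.0:
            t, praw = (0.0, 1.0) if np.mean(a) == np.mean(b) else (np.inf, 0.0)
        else:
            t, praw = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "approach": approach,
                "percentile": percentile,
                "t_statistic": float(t),
                "p_raw": float(praw),
                "n_bimodal": len(a),
                "n_unimodal": len(b),
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_raw"].to_numpy(), method="holm")[1]
    return out
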