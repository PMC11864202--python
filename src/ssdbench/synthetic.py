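"""Synthetic toxicity-study generator.

Emulates the statistical structure of a curated acute ecotoxicity
compilation so the whole pipeline runs without any external download: per
chemical, >50 species spanning 3-4 taxonomic groups, species-level
sensitivity drawn on the log10 concentration scale from either a
log-normal distribution or a two-component log-normal mixture (a small
hypersensitive component mimicking, e.g., daphniids that are far more
sensitive to aniline than all other taxa), and several records per species
multiplied by log-normal noise so the geometric-mean collapse is
exercised. The analytic quantiles of the generating marginal are returned
as ground truth for recovery checks.

Default magnitudes (configurable): unimodal mu = 1.5, sigma = 0.8 on
log10 ug/L, spanning the 3-4 orders of magnitude typical of acute SSDs;
group weights algae 0.15 / invertebrate 0.35 / amphibian 0.10 / fish 0.40,
reflecting the invertebrate/fish dominance of acute test data; two records
per species with log10 noise SD 0.2 (about a factor 1.6 between-test
spread). These are pragmatic emulation choices, not estimates from any
particular database.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import optimize, special

from .exceptions import ConfigError, NumericError
from .ingest import EffectMeasure, TaxonGroup, ToxicityRecord

__all__ = [
    "LognormalModel",
    "MixtureModel",
    "SyntheticStudyConfig",
    "GroundTruth",
    "generate_chemical",
    "generate_study",
    "DEFAULT_GROUP_WEIGHTS",
]

DEFAULT_GROUP_WEIGHTS: Mapping[TaxonGroup, float] = {
    TaxonGroup.ALGAE: 0.15,
    TaxonGroup.INVERTEBRATE: 0.35,
    TaxonGroup.AMPHIBIAN: 0.10,
    TaxonGroup.FISH: 0.40,
}


@dataclass(frozen=True)
class LognormalModel:
    """Unimodal species-sensitivity model: log10(value) ~ N(mu, sigma^2)."""

    mu_log10: float = 1.5
    sigma_log10: float = 0.8

    def __post_init__(self) -> None:
        if self.sigma_log10 <= 0:
            raise ConfigError("sigma_log10 must be > 0")

    def quantile(self, p: float) -> float:
        return float(10.0 ** (self.mu_log10 + self.sigma_log10 * special.ndtri(p)))

    def draw_log10(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.mu_log10 + self.sigma_log10 * rng.standard_normal(n)


@dataclass(frozen=True)
class MixtureModel:
    """Two-component log10-normal mixture; component 1 is the sensitive one.

    When ``sensitive_group`` is set, species drawn from component 1 receive
    that taxonomic group label (component-linked assignment), mimicking a
    taxon-specific mode of action.
    """

    weight_sensitive: float = 0.1
    mu1: float = 0.0
    sigma1: float = 0.3
    mu2: float = 3.0
    sigma2: float = 0.3
    sensitive_group: Optional[TaxonGroup] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight_sensitive <= 1.0):
            raise ConfigError("weight_sensitive must lie in [0, 1]")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ConfigError("mixture sigmas must be > 0")
        if self.weight_sensitive > 0 and not (self.mu1 < self.mu2):
            raise ConfigError("mixture means must be ordered mu1 < mu2")

    def cdf_log10(self, y: float) -> float:
        w = self.weight_sensitive
        return float(
            w * special.ndtr((y - self.mu1) / self.sigma1)
            + (1.0 - w) * special.ndtr((y - self.mu2) / self.sigma2)
        )

    def quantile(self, p: float) -> float:
        """Analytic p-quantile of the mixture marginal (bisection on the CDF)."""
        if self.weight_sensitive == 0.0:
            return LognormalModel(self.mu2, self.sigma2).quantile(p)
        lo = min(self.mu1 - 10 * self.sigma1, self.mu2 - 10 * self.sigma2)
        hi = max(self.mu1 + 10 * self.sigma1, self.mu2 + 10 * self.sigma2)
        y = optimize.brentq(lambda t: self.cdf_log10(t) - p, lo, hi, xtol=1e-12)
        return float(10.0**y)

    def draw_log10(
        self, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (log10 values, component flags); flag True = sensitive."""
        sens = rng.random(n) < self.weight_sensitive
        y = np.where(
            sens,
            self.mu1 + self.sigma1 * rng.standard_normal(n),
            self.mu2 + self.sigma2 * rng.standard_normal(n),
        )
        return y, sens


SensitivityModel = Union[LognormalModel, MixtureModel]


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Full recipe for a synthetic multi-chemical study."""

    n_chemicals: int = 35
    n_species: int = 60
    group_weights: Mapping[TaxonGroup, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_WEIGHTS)
    )
    sensitivity_model: SensitivityModel = field(default_factory=LognormalModel)
    records_per_species: int = 2
    record_noise_sd_log10: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chemicals < 1:
            raise ConfigError("n_chemicals must be >= 1")
        if self.n_species < 4:
            raise ConfigError("n_species must be >= 4")
        total = sum(self.group_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"group_weights must sum to 1, got {total}")
        if self.records_per_species < 1:
            raise ConfigError("records_per_species must be >= 1")
        if self.record_noise_sd_log10 < 0:
            raise ConfigError("record_noise_sd_log10 must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic quantiles of the generating marginal, for recovery checks."""

    chemical_id: str
    true_hc: Mapping[float, float]
    generating_params: Mapping

    def __post_init__(self) -> None:
        ps = sorted(self.true_hc)
        vals = [self.true_hc[p] for p in ps]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise NumericError("ground-truth quantiles must increase with p")


_GROUPS = tuple(TaxonGroup)
_LN10 = float(np.log(10.0))


def _assign_groups(
    n: int,
    weights: Mapping[TaxonGroup, float],
    sensitive: Optional[np.ndarray],
    sensitive_group: Optional[TaxonGroup],
    rng: np.random.Generator,
) -> list[TaxonGroup]:
    p = np.array([weights.get(g, 0.0) for g in _GROUPS])
    for _ in range(100):
        idx = rng.choice(len(_GROUPS), size=n, p=p)
        groups = [_GROUPS[i] for i in idx]
        if sensitive is not None and sensitive_group is not None:
            groups = [
                sensitive_group if s else g for g, s in zip(groups, sensitive)
            ]
        if len(set(groups)) >= 3:
            return groups
    raise ConfigError(
        "group weights produced fewer than 3 nonempty groups in 100 attempts"
    )


def generate_chemical(
    config: SyntheticStudyConfig,
    rng: np.random.Generator,
    chemical_id: str = "chem_001",
) -> tuple[list[ToxicityRecord], GroundTruth]:
    """Generate all records for one chemical plus its analytic ground truth."""
    model = config.sensitivity_model
    n = config.n_species
    if isinstance(model, MixtureModel):
        y, sens = model.draw_log10(n, rng)
        sensitive_group = model.sensitive_group
    else:
        y = model.draw_log10(n, rng)
        sens, sensitive_group = None, None
    groups = _assign_groups(n, config.group_weights, sens, sensitive_group, rng)
    species = [f"sp_{i + 1:04d}" for i in range(n)]

    records: list[ToxicityRecord] = []
    for i in range(n):
        # algae tests report growth inhibition EC50s; animal tests LC50s
        measure = (
            EffectMeasure.EC50 if groups[i] is TaxonGroup.ALGAE else EffectMeasure.LC50
        )
        noise = config.record_noise_sd_log10 * rng.standard_normal(
            config.records_per_species
        )
        for r in range(config.records_per_species):
            records.append(
                ToxicityRecord(
                    chemical_id=chemical_id,
                    species=species[i],
                    taxon_group=groups[i],
                    effect_measure=measure,
                    concentration=float(10.0 ** (y[i] + noise[r])),
                )
            )

    truth = GroundTruth(
        chemical_id=chemical_id,
        true_hc={p: model.quantile(p) for p in (0.01, 0.05, 0.5)},
        generating_params=_model_params(model),
    )
    return records, truth


def _model_params(model: SensitivityModel) -> dict:
    if isinstance(model, MixtureModel):
        return {
            "model": "mixture",
            "weight_sensitive": model.weight_sensitive,
            "mu1": model.mu1,
            "sigma1": model.sigma1,
            "mu2": model.mu2,
            "sigma2": model.sigma2,
            "sensitive_group": model.sensitive_group.value
            if model.sensitive_group
            else None,
        }
    return {
        "model": "lognormal",
        "mu_log10": model.mu_log10,
        "sigma_log10": model.sigma_log10,
    }


def records_to_csv(records: Sequence[ToxicityRecord], path) -> None:
    """Write records in the CSV schema the ingest layer reads (ug/L)."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "chemical_id": r.chemical_id,
                "species": r.species,
                "taxon_group": r.taxon_group.value,
                "effect_measure": r.effect_measure.value,
                "concentration": repr(r.concentration),
                "unit": "ug/L",
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def generate_study(
    config: SyntheticStudyConfig, outdir
) -> tuple[list[Path], Path]:
    """Generate a whole study: one toxicity CSV per chemical + ground truth.

    Reproducible from ``config.seed``: chemical i uses the substream
    ``default_rng([seed, i])``, so adding chemicals never reshuffles
    earlier ones.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_paths: list[Path] = []
    truths: dict[str, dict] = {}
    for i in range(config.n_chemicals):
        cid = f"chem_{i + 1:03d}"
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, i])
        records, truth = generate_chemical(config, rng, chemical_id=cid)
        path = outdir / f"{cid}.csv"
        records_to_csv(records, path)
        csv_paths.append(path)
        truths[cid] = {
            "true_hc": {str(p): v for p, v in truth.true_hc.items()},
            "generating_params": dict(truth.generating_params),
        }
    truth_path = outdir / "ground_truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(truths, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return csv_paths, truth_path
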