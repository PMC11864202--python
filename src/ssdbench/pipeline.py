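"""End-to-end orchestration: simulate -> ingest -> benchmark -> summarize
-> compare, with a content-hashed artifact manifest.

All outputs are plain CSV/JSON with deterministic content for a fixed
config and seed, so two runs of the same configuration produce
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .benchmark import (
    BimodalityResult,
    SubsampleSpec,
    aggregate_across_chemicals,
    bimodality_coefficient,
    compare_groups,
    records_to_frame,
    run_benchmark,
    summaries_to_frame,
    summarize_deviations,
)
from .config import RunConfig
from .exceptions import ConfigError, InsufficientDataError
from .ingest import (
    ChemicalDataset,
    apply_solubility_filter,
    collapse_all,
    read_solubility_table,
    read_toxicity_table,
    select_chemicals,
    write_species_table,
    write_validation_report,
)
from .synthetic import LognormalModel, MixtureModel, SyntheticStudyConfig, generate_study
from .ingest import TaxonGroup

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineResult", "ingest_stage", "synthetic_config_from_mapping"]


@dataclass
class PipelineResult:
    """Artifact manifest of one pipeline run."""

    outdir: Path
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def synthetic_config_from_mapping(raw: dict, seed: int) -> SyntheticStudyConfig:
    """Build a SyntheticStudyConfig from the `synthetic:` config block."""
    raw = dict(raw)
    model_raw = raw.pop("sensitivity_model", None)
    if model_raw is None:
        model = LognormalModel()
    elif model_raw.get("model", "lognormal") == "lognormal":
        model = LognormalModel(
            mu_log10=float(model_raw.get("mu_log10", 1.5)),
            sigma_log10=float(model_raw.get("sigma_log10", 0.8)),
        )
    elif model_raw["model"] == "mixture":
        sg = model_raw.get("sensitive_group")
        model = MixtureModel(
            weight_sensitive=float(model_raw.get("weight_sensitive", 0.1)),
            mu1=float(model_raw.get("mu1", 0.0)),
            sigma1=float(model_raw.get("sigma1", 0.3)),
            mu2=float(model_raw.get("mu2", 3.0)),
            sigma2=float(model_raw.get("sigma2", 0.3)),
            sensitive_group=TaxonGroup(sg) if sg else None,
        )
    else:
        raise ConfigError(f"unknown sensitivity model {model_raw.get('model')!r}")
    gw = raw.pop("group_weights", None)
    kwargs = dict(
        sensitivity_model=model,
        seed=seed,
        n_chemicals=int(raw.pop("n_chemicals", 35)),
        n_species=int(raw.pop("n_species", 60)),
        records_per_species=int(raw.pop("records_per_species", 2)),
        record_noise_sd_log10=float(raw.pop("record_noise_sd_log10", 0.2)),
    )
    if gw is not None:
        kwargs["group_weights"] = {TaxonGroup(k): float(v) for k, v in gw.items()}
    if raw:
        raise ConfigError(f"unknown synthetic config keys {sorted(raw)}")
    return SyntheticStudyConfig(**kwargs)


def ingest_stage(
    config: RunConfig, input_paths: Sequence[Path], outdir: Path
) -> list[ChemicalDataset]:
    """Read, filter, collapse, and select; write the species table + report."""
    records = []
    report = []
    for path in input_paths:
        recs, rep = read_toxicity_table(path)
        records.extend(recs)
        report.extend({"file": Path(path).name, **r} for r in rep)
    if config.solubility:
        entries = read_solubility_table(config.solubility)
        records = apply_solubility_filter(records, entries, config.solubility_factor)
    datasets = collapse_all(records)
    selected = select_chemicals(datasets, config.min_species, config.min_groups)
    if len(selected) < len(datasets):
        logger.info(
            "selection kept %d of %d chemicals (>= %d species, >= %d groups)",
            len(selected),
            len(datasets),
            config.min_species,
            config.min_groups,
        )
    write_species_table(selected, outdir / "species_table.csv")
    write_validation_report(report, outdir / "validation_report.jsonl")
    return selected


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the configured study end to end and write all artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.inputs:
        input_paths = [Path(p) for p in config.inputs]
    else:
        syn = synthetic_config_from_mapping(dict(config.synthetic), config.seed)
        data_dir = outdir / "data"
        input_paths, _ = generate_study(syn, data_dir)

    datasets = ingest_stage(config, input_paths, outdir)
    if not datasets:
        raise InsufficientDataError("no chemical passed the selection criteria")

    bimod = [
        bimodality_coefficient(
            d.values,
            log_transform=config.bimodality_log_transform,
            chemical_id=d.chemical_id,
        )
        for d in datasets
    ]
    _write_bimodality(bimod, outdir / "bimodality.csv")

    dev_frames, sum_frames, agg_frames, cmp_frames = [], [], [], []
    all_summaries_by_key: dict[tuple[int, float], list] = {}
    for size in config.sizes:
        for p in config.p_targets:
            spec = SubsampleSpec(
                size=size,
                iterations=config.iterations,
                min_groups=config.min_groups,
                seed=config.seed,
            )
            summaries = []
            for d in datasets:
                recs = run_benchmark(
                    d,
                    spec,
                    p=p,
                    families=config.families,
                    averaging_method=config.averaging_method,
                    quantile_method=config.quantile_method,
                )
                df = records_to_frame(recs)
                df.insert(0, "size", size)
                dev_frames.append(df)
                summaries.extend(summarize_deviations(recs, config.quantile_method))
            all_summaries_by_key[(size, p)] = summaries
            sdf = summaries_to_frame(summaries)
            sdf.insert(0, "size", size)
            sdf.insert(1, "p", p)
            sum_frames.append(sdf)
            adf = aggregate_across_chemicals(summaries)
            adf.insert(0, "size", size)
            adf.insert(1, "p", p)
            agg_frames.append(adf)

    pd.concat(dev_frames, ignore_index=True).to_csv(outdir / "deviations.csv", index=False)
    pd.concat(sum_frames, ignore_index=True).to_csv(outdir / "summary.csv", index=False)
    pd.concat(agg_frames, ignore_index=True).to_csv(outdir / "aggregate.csv", index=False)

    n_bimodal = sum(b.bimodal for b in bimod)
    comparison_done = False
    if 2 <= n_bimodal <= len(bimod) - 2:
        size = max(config.sizes)
        p = config.p_targets[0]
        for pct in config.comparison_percentiles:
            cdf = compare_groups(all_summaries_by_key[(size, p)], bimod, pct)
            cdf.insert(0, "size", size)
            cdf.insert(1, "p", p)
            cmp_frames.append(cdf)
        comparison_done = True
    else:
        logger.info(
            "group comparison skipped: %d bimodal of %d chemicals (need >= 2 per group)",
            n_bimodal,
            len(bimod),
        )
    if cmp_frames:
        pd.concat(cmp_frames, ignore_index=True).to_csv(
            outdir / "comparison.csv", index=False
        )

    artifacts = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        if p.name != "manifest.json"
    )
    manifest = {
        "seed": config.seed,
        "sizes": list(config.sizes),
        "iterations": config.iterations,
        "p_targets": list(config.p_targets),
        "averaging_method": config.averaging_method,
        "n_chemicals": len(datasets),
        "n_bimodal": int(n_bimodal),
        "comparison_done": comparison_done,
        "files": {a: _sha256(outdir / a) for a in artifacts},
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(outdir=outdir, manifest=manifest)


def _write_bimodality(results: Sequence[BimodalityResult], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "chemical_id": b.chemical_id,
                "n": b.n,
                "skewness": b.skewness,
                "excess_kurtosis": b.excess_kurtosis,
                "bc": b.bc,
                "bimodal": b.bimodal,
            }
            for b in results
        ]
    ).to_csv(path, index=False)
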