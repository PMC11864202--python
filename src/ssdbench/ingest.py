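"""Reading, validating, filtering and collapsing raw ecotoxicity records.

The raw input is a per-record table: one acute toxicity test result
(EC50 or LC50, a concentration) for one species of one chemical, with a
taxonomic group label (algae, invertebrate, amphibian, fish). The pipeline
works on the species level: multiple records per species are collapsed to
their geometric mean, records exceeding five times the chemical's water
solubility are dropped first, and only chemicals with data for at least 51
species spanning at least three of the four taxonomic groups qualify for
the benchmark. The nonparametric reference HC_p for a qualifying chemical
is the empirical p-th percentile of its species geometric means.

Concentrations are held internally in ug/L; mg/L input is converted, any
other unit is rejected at read time.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DataInconsistencyError,
    DomainError,
    InsufficientDataError,
    RowValidationError,
    SchemaError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonGroup",
    "EffectMeasure",
    "ToxicityRecord",
    "SolubilityEntry",
    "ChemicalDataset",
    "read_toxicity_table",
    "read_solubility_table",
    "apply_solubility_filter",
    "collapse_to_species",
    "collapse_all",
    "select_chemicals",
    "reference_hc",
    "write_species_table",
    "write_validation_report",
    "QUANTILE_METHODS",
]


class TaxonGroup(str, enum.Enum):
    ALGAE = "algae"
    INVERTEBRATE = "invertebrate"
    AMPHIBIAN = "amphibian"
    FISH = "fish"


class EffectMeasure(str, enum.Enum):
    EC50 = "EC50"
    LC50 = "LC50"


class Medium(str, enum.Enum):
    FRESHWATER = "freshwater"
    SALTWATER = "saltwater"


# tolerated spellings -> canonical group
_GROUP_ALIASES = {
    "algae": TaxonGroup.ALGAE,
    "alga": TaxonGroup.ALGAE,
    "invertebrate": TaxonGroup.INVERTEBRATE,
    "invertebrates": TaxonGroup.INVERTEBRATE,
    "amphibian": TaxonGroup.AMPHIBIAN,
    "amphibians": TaxonGroup.AMPHIBIAN,
    "fish": TaxonGroup.FISH,
}

# accepted unit spellings -> factor converting to ug/L
_UNIT_FACTORS = {
    "ug/l": 1.0,
    "µg/l": 1.0,  # µg/L
    "μg/l": 1.0,  # Greek mu
    "mg/l": 1000.0,
}


@dataclass(frozen=True)
class ToxicityRecord:
    """One validated acute toxicity test record, concentration in ug/L."""

    chemical_id: str
    species: str
    taxon_group: TaxonGroup
    effect_measure: EffectMeasure
    concentration: float
    medium: Optional[Medium] = None
    use_group: Optional[str] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.concentration) and self.concentration > 0):
            raise RowValidationError(
                f"concentration must be positive and finite, got {self.concentration}"
            )


@dataclass(frozen=True)
class SolubilityEntry:
    """Water solubility of one chemical, ug/L."""

    chemical_id: str
    water_solubility: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.water_solubility) and self.water_solubility > 0):
            raise RowValidationError("water_solubility must be positive and finite")


@dataclass(frozen=True)
class ChemicalDataset:
    """Species-level dataset for one chemical: one geometric mean per species."""

    chemical_id: str
    species_values: tuple[tuple[str, TaxonGroup, float], ...]

    def __post_init__(self) -> None:
        names = [s for s, _, _ in self.species_values]
        if len(set(names)) != len(names):
            raise DataInconsistencyError(
                f"duplicate species in dataset {self.chemical_id}"
            )
        for _, _, v in self.species_values:
            if not (math.isfinite(v) and v > 0):
                raise RowValidationError("geomean concentrations must be positive")

    @property
    def n_species(self) -> int:
        return len(self.species_values)

    @property
    def n_groups(self) -> int:
        return len({g for _, g, _ in self.species_values})

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, _, v in self.species_values], dtype=float)

    @property
    def groups(self) -> tuple[TaxonGroup, ...]:
        return tuple(g for _, g, _ in self.species_values)

    def subset(self, indices: Sequence[int]) -> "ChemicalDataset":
        return ChemicalDataset(
            self.chemical_id,
            tuple(self.species_values[i] for i in indices),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chemical_id": self.chemical_id,
                    "species": s,
                    "taxon_group": g.value,
                    "geomean_ugL": v,
                }
                for s, g, v in self.species_values
            ]
        )


DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "chemical": "chemical_id",
    "species": "species",
    "group": "taxon_group",
    "measure": "effect_measure",
    "concentration": "concentration",
    "unit": "unit",
}

_MANDATORY = ("chemical", "species", "group", "measure", "concentration", "unit")


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")


def read_toxicity_table(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    on_invalid: str = "drop",
) -> tuple[list[ToxicityRecord], list[dict]]:
    """Read a delimited toxicity table into validated records.

    Parameters
    ----------
    path : CSV (or TSV, by extension) file with a header row.
    column_map : mapping from the canonical keys ``chemical, species, group,
        measure, concentration, unit`` (optionally ``medium, use_group``)
        to the column names in the file. Defaults to the schema written by
        the synthetic-data generator.
    on_invalid : ``"drop"`` collects row-level failures in the returned
        validation report and skips the rows; ``"error"`` raises on the
        first invalid row.

    Returns
    -------
    (records, report) where report is a list of ``{"row": i, "reason": str}``
    objects, row indices 0-based over data rows, order preserved.
    """
    if on_invalid not in ("drop", "error"):
        raise DomainError(f"on_invalid must be 'drop' or 'error', got {on_invalid!r}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = _read_table(path)
    for key in _MANDATORY:
        if cmap[key] not in df.columns:
            raise SchemaError(
                f"mandatory column {cmap[key]!r} (role {key!r}) missing from {path.name}"
            )

    records: list[ToxicityRecord] = []
    report: list[dict] = []

    def fail(i: int, reason: str) -> None:
        if on_invalid == "error":
            raise RowValidationError(f"row {i}: {reason}")
        report.append({"row": int(i), "reason": reason})

    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        try:
            raw_conc = rowd[cmap["concentration"]]
            conc = float(raw_conc)
        except (TypeError, ValueError):
            fail(i, f"non-numeric concentration {rowd[cmap['concentration']]!r}")
            continue
        unit = str(rowd[cmap["unit"]]).strip().lower()
        if unit not in _UNIT_FACTORS:
            fail(i, f"unsupported unit {rowd[cmap['unit']]!r} (accepted: ug/L, mg/L)")
            continue
        group_raw = str(rowd[cmap["group"]]).strip().lower()
        if group_raw not in _GROUP_ALIASES:
            fail(i, f"unknown taxonomic group {rowd[cmap['group']]!r}")
            continue
        measure_raw = str(rowd[cmap["measure"]]).strip().upper()
        if measure_raw not in (m.value for m in EffectMeasure):
            fail(i, f"unknown effect measure {rowd[cmap['measure']]!r}")
            continue
        medium = None
        if "medium" in cmap and cmap["medium"] in df.columns:
            raw = rowd[cmap["medium"]]
            if isinstance(raw, str) and raw.strip():
                try:
                    medium = Medium(raw.strip().lower())
                except ValueError:
                    fail(i, f"unknown medium {raw!r}")
                    continue
        use_group = None
        if "use_group" in cmap and cmap["use_group"] in df.columns:
            raw = rowd[cmap["use_group"]]
            if isinstance(raw, str) and raw.strip():
                use_group = raw.strip()
        try:
            records.append(
                ToxicityRecord(
                    chemical_id=str(rowd[cmap["chemical"]]).strip(),
                    species=str(rowd[cmap["species"]]).strip(),
                    taxon_group=_GROUP_ALIASES[group_raw],
                    effect_measure=EffectMeasure(measure_raw),
                    concentration=conc * _UNIT_FACTORS[unit],
                    medium=medium,
                    use_group=use_group,
                )
            )
        except RowValidationError as exc:
            fail(i, str(exc))
    return records, report


def read_solubility_table(
    path, column_map: Optional[Mapping[str, str]] = None
) -> list[SolubilityEntry]:
    """Read a per-chemical water-solubility table (columns chemical, solubility, unit)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"solubility file not found: {path}")
    cmap = {"chemical": "chemical_id", "solubility": "water_solubility", "unit": "unit"}
    if column_map:
        cmap.update(column_map)
    df = _read_table(path)
    for key in ("chemical", "solubility", "unit"):
        if cmap[key] not in df.columns:
            raise SchemaError(f"mandatory column {cmap[key]!r} missing")
    entries = []
    for _, row in df.iterrows():
        unit = str(row[cmap["unit"]]).strip().lower()
        if unit not in _UNIT_FACTORS:
            raise RowValidationError(f"unsupported solubility unit {row[cmap['unit']]!r}")
        entries.append(
            SolubilityEntry(
                chemical_id=str(row[cmap["chemical"]]).strip(),
                water_solubility=float(row[cmap["solubility"]]) * _UNIT_FACTORS[unit],
            )
        )
    return entries


def apply_solubility_filter(
    records: Iterable[ToxicityRecord],
    solubility: Iterable[SolubilityEntry],
    factor: float = 5.0,
) -> list[ToxicityRecord]:
    """Drop records whose concentration strictly exceeds factor x solubility.

    Values exactly equal to the bound are kept ("exceeded" is strict).
    Chemicals with no solubility entry pass through unfiltered with a
    logged warning — the curated sources apply this screen upstream.
    """
    if not (factor > 0):
        raise DomainError("factor must be > 0")
    limits = {e.chemical_id: factor * e.water_solubility for e in solubility}
    kept: list[ToxicityRecord] = []
    warned: set[str] = set()
    for rec in records:
        limit = limits.get(rec.chemical_id)
        if limit is None:
            if rec.chemical_id not in warned:
                logger.warning(
                    "no solubility entry for chemical %s; solubility filter skipped",
                    rec.chemical_id,
                )
                warned.add(rec.chemical_id)
            kept.append(rec)
        elif rec.concentration <= limit:
            kept.append(rec)
    return kept


def collapse_to_species(
    records: Iterable[ToxicityRecord], chemical_id: str
) -> ChemicalDataset:
    """Collapse records of one chemical to one geometric mean per species.

    A species listed under two different taxonomic groups is a data
    inconsistency and raises.
    """
    per_species: dict[str, list[float]] = {}
    group_of: dict[str, TaxonGroup] = {}
    order: list[str] = []
    for rec in records:
        if rec.chemical_id != chemical_id:
            continue
        if rec.species in group_of and group_of[rec.species] != rec.taxon_group:
            raise DataInconsistencyError(
                f"species {rec.species!r} of chemical {chemical_id!r} appears "
                f"under groups {group_of[rec.species].value!r} and "
                f"{rec.taxon_group.value!r}"
            )
        if rec.species not in per_species:
            per_species[rec.species] = []
            order.append(rec.species)
        group_of[rec.species] = rec.taxon_group
        per_species[rec.species].append(rec.concentration)
    if not per_species:
        raise InsufficientDataError(f"no records for chemical {chemical_id!r}")
    values = tuple(
        (
            sp,
            group_of[sp],
            float(np.exp(np.mean(np.log(per_species[sp])))),
        )
        for sp in order
    )
    return ChemicalDataset(chemical_id=chemical_id, species_values=values)


def collapse_all(records: Sequence[ToxicityRecord]) -> list[ChemicalDataset]:
    """Collapse a mixed-record list into one ChemicalDataset per chemical."""
    seen: list[str] = []
    for rec in records:
        if rec.chemical_id not in seen:
            seen.append(rec.chemical_id)
    return [collapse_to_species(records, cid) for cid in seen]


def select_chemicals(
    datasets: Iterable[ChemicalDataset],
    min_species: int = 51,
    min_groups: int = 3,
) -> list[ChemicalDataset]:
    """Keep chemicals with >= min_species species from >= min_groups groups.

    The defaults encode "more than 50 species from at least three of four
    taxonomic groups": enough data for a trustworthy nonparametric HC5.
    """
    if min_species < 1:
        raise DomainError("min_species must be >= 1")
    if not (1 <= min_groups <= 4):
        raise DomainError("min_groups must be in 1..4")
    return [
        d
        for d in datasets
        if d.n_species >= min_species and d.n_groups >= min_groups
    ]


#: quantile dialects: name -> numpy.quantile method
QUANTILE_METHODS: Mapping[str, str] = {
    "linear_type7": "linear",
    "lower_empirical": "lower",
}


def empirical_quantile(
    values: np.ndarray, p: float, quantile_method: str = "linear_type7"
) -> float:
    """Empirical quantile under a named convention (default: linear type 7)."""
    if quantile_method not in QUANTILE_METHODS:
        raise DomainError(
            f"unknown quantile_method {quantile_method!r}; "
            f"allowed: {sorted(QUANTILE_METHODS)}"
        )
    return float(np.quantile(np.asarray(values, float), p, method=QUANTILE_METHODS[quantile_method]))


def reference_hc(
    dataset: ChemicalDataset,
    p: float = 0.05,
    quantile_method: str = "linear_type7",
) -> float:
    """Nonparametric reference HC_p: the empirical p-th percentile of the
    species geometric means (default convention: linear interpolation of
    order statistics, h = (n-1)p + 1)."""
    if not (0.0 < p < 1.0):
        raise DomainError("p must lie in (0, 1)")
    if dataset.n_species < 2:
        raise InsufficientDataError(
            f"reference percentile needs >= 2 species, got {dataset.n_species}"
        )
    return empirical_quantile(dataset.values, p, quantile_method)


def write_species_table(datasets: Iterable[ChemicalDataset], path) -> None:
    """Write the validated species-level table as CSV."""
    frames = [d.to_frame() for d in datasets]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_species_table(path) -> list[ChemicalDataset]:
    """Read back a species-level CSV written by :func:`write_species_table`."""
    df = pd.read_csv(path)
    datasets = []
    for cid, sub in df.groupby("chemical_id", sort=False):
        values = tuple(
            (str(r.species), TaxonGroup(r.taxon_group), float(r.geomean_ugL))
            for r in sub.itertuples(index=False)
        )
        datasets.append(ChemicalDataset(chemical_id=str(cid), species_values=values))
    return datasets


def write_validation_report(report: Sequence[dict], path) -> None:
    """Write the row-level validation report as JSON lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for entry in report:
            fh.write(json.dumps(entry) + "\n")
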