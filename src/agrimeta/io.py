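"""Study-table data model, CSV reading/writing and variance-measure conversion.

The tabular input has one row per observation (a publication may contribute
several observations).  Rows that violate the inclusion rules are never
silently dropped: they are collected into a structured rejection report so
the analytic sample remains auditable.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

__all__ = [
    "StudyRecord",
    "VarianceMeasure",
    "Rejection",
    "ParseResult",
    "SchemaError",
    "read_study_table",
    "write_study_table",
    "to_sd",
    "schema_description",
    "COLUMNS",
    "TAXON_GROUPS",
    "FUNCTIONAL_GROUPS",
    "CROP_TYPES",
    "SCALES",
]

TAXON_GROUPS = ("arthropods", "birds", "microbes", "plants")
#: taxa recorded in the literature but excluded for small sample size (n < 5)
EXCLUDED_TAXA = ("earthworms", "mammals", "nematodes", "protozoa")
FUNCTIONAL_GROUPS = (
    "producers", "herbivores", "pollinators", "predators", "decomposers", "other",
)
CROP_TYPES = ("cereals", "grassland", "mixed", "orchard", "vegetables", "miscellaneous")
SCALES = ("plot", "field", "farm")

# Normalisation map for level spellings that occur in source material.
SYNONYMS = {
    "grasses": "grassland",
    "pasture": "grassland",
    "unspecified": "miscellaneous",
    "misc": "miscellaneous",
    "others": "other",
    "arthropod": "arthropods",
    "bird": "birds",
    "plant": "plants",
    "microbe": "microbes",
    "vegetable": "vegetables",
    "cereal": "cereals",
}

COLUMNS = (
    "publication_id", "observation_id", "pub_year", "country", "region",
    "taxon_group", "functional_group", "crop_type", "scale",
    "mean_org", "sd_org", "n_org", "mean_conv", "sd_conv", "n_conv",
    "pct_arable", "n_habitats", "avg_field_size",
)

_LANDSCAPE_COLS = ("pct_arable", "n_habitats", "avg_field_size")


class SchemaError(ValueError):
    """Raised when the input file does not match the documented schema."""


@dataclass
class StudyRecord:
    """One observation: arm-level richness summaries plus covariates."""

    publication_id: str
    observation_id: str
    pub_year: int
    country: str
    region: str
    taxon_group: str
    functional_group: str
    crop_type: str
    scale: str
    mean_org: float
    sd_org: float
    n_org: int
    mean_conv: float
    sd_conv: float
    n_conv: int
    pct_arable: float | None = None
    n_habitats: float | None = None
    avg_field_size: float | None = None
    richness_surrogate: bool = False
    landscape_imputed: bool = False

    def has_landscape(self) -> bool:
        return all(
            getattr(self, c) is not None and not math.isnan(getattr(self, c))
            for c in _LANDSCAPE_COLS
        )


@dataclass
class VarianceMeasure:
    """A dispersion statistic as reported in a source publication."""

    kind: str  # one of {"sd", "se", "ci95_halfwidth", "variance"}
    value: float
    n: int = 0


@dataclass
class Rejection:
    row: int
    reason: str


@dataclass
class ParseResult:
    records: list[StudyRecord] = field(default_factory=list)
    rejections: list[Rejection] = field(default_factory=list)


def to_sd(m: VarianceMeasure) -> float:
    """Convert a reported variance measure to a standard deviation.

    ``se`` multiplies by sqrt(n); a 95% CI half-width divides out the
    two-sided t quantile at n-1 df before scaling by sqrt(n).
    """
    if m.value < 0:
        raise ValueError(f"variance measure must be nonnegative, got {m.value}")
    if m.kind == "sd":
        return float(m.value)
    if m.kind == "variance":
        return math.sqrt(m.value)
    if m.kind == "se":
        if m.n < 2:
            raise ValueError("se conversion requires n >= 2")
        return float(m.value * math.sqrt(m.n))
    if m.kind == "ci95_halfwidth":
        if m.n < 2:
            raise ValueError("ci95_halfwidth conversion requires n >= 2")
        t = stats.t.ppf(0.975, m.n - 1)
        return float(m.value * math.sqrt(m.n) / t)
    raise ValueError(f"unknown variance measure kind {m.kind!r}")


def _norm_number(text: str) -> float:
    # middle-dot decimal marks are normalised to "."
    return float(text.strip().replace("·", "."))


def _norm_level(text: str, allowed: Sequence[str], column: str) -> str:
    level = text.strip().lower()
    level = SYNONYMS.get(level, level)
    if level not in allowed:
        raise ValueError(f"unknown {column} level {text.strip()!r}")
    return level


def _parse_row(row: dict[str, str], line: int) -> StudyRecord:
    taxon_raw = row["taxon_group"].strip().lower()
    taxon_raw = SYNONYMS.get(taxon_raw, taxon_raw)
    if taxon_raw in EXCLUDED_TAXA:
        raise ValueError(f"taxon group {taxon_raw!r} excluded (small sample size)")
    rec = StudyRecord(
        publication_id=row["publication_id"].strip(),
        observation_id=row["observation_id"].strip(),
        pub_year=int(_norm_number(row["pub_year"])),
        country=row["country"].strip(),
        region=row.get("region", "").strip(),
        taxon_group=_norm_level(row["taxon_group"], TAXON_GROUPS, "taxon_group"),
        functional_group=_norm_level(
            row["functional_group"], FUNCTIONAL_GROUPS, "functional_group"
        ),
        crop_type=_norm_level(row["crop_type"], CROP_TYPES, "crop_type"),
        scale=_norm_level(row["scale"], SCALES, "scale"),
        mean_org=_norm_number(row["mean_org"]),
        sd_org=_norm_number(row["sd_org"]),
        n_org=int(_norm_number(row["n_org"])),
        mean_conv=_norm_number(row["mean_conv"]),
        sd_conv=_norm_number(row["sd_conv"]),
        n_conv=int(_norm_number(row["n_conv"])),
        richness_surrogate=row.get("richness_surrogate", "").strip().lower()
        in ("1", "true", "yes"),
    )
    landscape = [row.get(c, "").strip() for c in _LANDSCAPE_COLS]
    present = [v != "" for v in landscape]
    if any(present) and not all(present):
        raise ValueError("landscape covariates must be all present or all missing")
    if all(present):
        rec.pct_arable = _norm_number(landscape[0])
        rec.n_habitats = _norm_number(landscape[1])
        rec.avg_field_size = _norm_number(landscape[2])
    _validate(rec)
    return rec


def _validate(rec: StudyRecord) -> None:
    if rec.n_org <= 1 or rec.n_conv <= 1:
        raise ValueError("n must exceed 1")
    if rec.mean_org <= 0 or rec.mean_conv <= 0:
        raise ValueError("arm means must be > 0")
    if rec.sd_org < 0 or rec.sd_conv < 0:
        raise ValueError("arm SDs must be >= 0")
    if rec.pct_arable is not None and not 0 <= rec.pct_arable <= 100:
        raise ValueError("pct_arable must lie in [0, 100]")
    if rec.n_habitats is not None and rec.n_habitats < 1:
        raise ValueError("n_habitats must be >= 1")
    if rec.avg_field_size is not None and rec.avg_field_size <= 0:
        raise ValueError("avg_field_size must be > 0")


def read_study_table(path: str | Path, *, delimiter: str = ",") -> ParseResult:
    """Read a study CSV into records plus a rejection report.

    Raises :class:`SchemaError` if a mandatory column is missing; rows that
    fail inclusion rules or fail to parse land in ``result.rejections``.
    """
    path = Path(path)
    result = ParseResult()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise SchemaError("empty file: no header row")
        header = {name.strip().lower(): name for name in reader.fieldnames}
        mandatory = [c for c in COLUMNS if c not in _LANDSCAPE_COLS and c != "region"]
        for col in mandatory:
            if col not in header:
                raise SchemaError(f"missing mandatory column: {col}")
        for i, raw in enumerate(reader, start=2):
            row = {
                key: (raw.get(orig) or "")
                for key, orig in header.items()
            }
            try:
                result.records.append(_parse_row(row, i))
            except (ValueError, KeyError) as exc:
                result.rejections.append(Rejection(row=i, reason=str(exc)))
    return result


def write_study_table(records: Iterable[StudyRecord], path: str | Path) -> None:
    """Write records back to CSV using the documented column layout."""
    path = Path(path)
    cols = COLUMNS + ("richness_surrogate",)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rec in records:
            d = asdict(rec)
            row = []
            for c in cols:
                v = d[c]
                if v is None:
                    v = ""
                elif c == "richness_surrogate":
                    v = "1" if v else "0"
                row.append(v)
            writer.writerow(row)


def write_rejection_report(rejections: Iterable[Rejection], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "reason"])
        for rej in rejections:
            writer.writerow([rej.row, rej.reason])


def schema_description() -> dict:
    """Machine-readable description of the study-table schema."""
    return {
        "format": "csv",
        "encoding": "utf-8",
        "columns": [
            {"name": "publication_id", "type": "string", "required": True},
            {"name": "observation_id", "type": "string", "required": True},
            {"name": "pub_year", "type": "integer", "required": True},
            {"name": "country", "type": "string", "required": True},
            {"name": "region", "type": "string", "required": False},
            {"name": "taxon_group", "type": "enum", "levels": list(TAXON_GROUPS)},
            {"name": "functional_group", "type": "enum", "levels": list(FUNCTIONAL_GROUPS)},
            {"name": "crop_type", "type": "enum", "levels": list(CROP_TYPES)},
            {"name": "scale", "type": "enum", "levels": list(SCALES)},
            {"name": "mean_org", "type": "number", "constraint": "> 0"},
            {"name": "sd_org", "type": "number", "constraint": ">= 0"},
            {"name": "n_org", "type": "integer", "constraint": "> 1"},
            {"name": "mean_conv", "type": "number", "constraint": "> 0"},
            {"name": "sd_conv", "type": "number", "constraint": ">= 0"},
            {"name": "n_conv", "type": "integer", "constraint": "> 1"},
            {"name": "pct_arable", "type": "number", "constraint": "[0, 100]",
             "required": False},
            {"name": "n_habitats", "type": "number", "constraint": ">= 1",
             "required": False},
            {"name": "avg_field_size", "type": "number", "constraint": "> 0 (ha)",
             "required": False},
        ],
        "notes": "landscape covariates must be all present or all missing per row",
    }


def write_schema(path: str | Path) -> None:
    Path(path).write_text(json.dumps(schema_description(), indent=2))
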