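"""Reading, validating and writing occurrence tables, transactions and rules.

Two CSV dialects are supported for occurrence tables:

``plain``
    columns ``species_name, latitude, longitude``
``gbif``
    the GBIF occurrence-export naming ``species, decimalLatitude,
    decimalLongitude``

Coordinates are WGS84 decimal degrees; rows with a blank species label,
non-numeric coordinates, or coordinates outside [-90, 90] x [-180, 180] are
dropped and counted rather than raising. Species labels are compared
case-sensitively after stripping surrounding whitespace.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .errors import EmptyInputError, FormatError, InputError

logger = logging.getLogger(__name__)

DIALECT_COLUMNS = {
    "plain": ("species_name", "latitude", "longitude"),
    "gbif": ("species", "decimalLatitude", "decimalLongitude"),
}

RULE_HEADER = (
    "antecedent",
    "consequent",
    "support",
    "confidence",
    "lift",
    "chi2",
    "p_value",
    "label",
)


@dataclass(frozen=True, order=True)
class OccurrenceRecord:
    """One georeferenced specimen: species label plus WGS84 lat/lon degrees."""

    species: str
    latitude: float
    longitude: float


@dataclass(frozen=True)
class BoundingBoxFilter:
    """Inclusive lat/lon box restricting one species to its native range."""

    species: str
    min_lat: float
    max_lat: float
    min_lon: float
    max_lon: float

    def __post_init__(self) -> None:
        if self.min_lat > self.max_lat or self.min_lon > self.max_lon:
            raise ValueError(
                f"bounding box for {self.species!r} has min > max "
                "(longitude wrap-around is not supported)"
            )

    def contains(self, lat: float, lon: float) -> bool:
        return (
            self.min_lat <= lat <= self.max_lat
            and self.min_lon <= lon <= self.max_lon
        )


@dataclass(frozen=True)
class ReadResult:
    """Parsed records plus bookkeeping on how many raw rows were dropped."""

    records: tuple[OccurrenceRecord, ...]
    n_dropped: int

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_coord(text: str, lo: float, hi: float) -> float | None:
    try:
        value = float(text)
    except (TypeError, ValueError):
        return None
    if not (lo <= value <= hi):
        return None
    return value


def read_occurrences(
    path: str | Path, dialect: Literal["plain", "gbif"] = "plain"
) -> ReadResult:
    """Read an occurrence CSV, dropping (and counting) malformed rows.

    Raises
    ------
    InputError
        if the file does not exist.
    FormatError
        if the dialect is unknown or required columns are missing.
    EmptyInputError
        if no row yields a valid record.
    """
    path = Path(path)
    if dialect not in DIALECT_COLUMNS:
        raise FormatError(f"unknown dialect {dialect!r}; expected 'plain' or 'gbif'")
    if not path.exists():
        raise InputError(f"occurrence file not found: {path}")

    sp_col, lat_col, lon_col = DIALECT_COLUMNS[dialect]
    records: list[OccurrenceRecord] = []
    n_dropped = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path} is empty (no header row)")
        missing = {sp_col, lat_col, lon_col}.difference(reader.fieldnames)
        if missing:
            raise FormatError(
                f"{path} lacks required column(s) {sorted(missing)} "
                f"for dialect {dialect!r}"
            )
        for row in reader:
            species = (row.get(sp_col) or "").strip()
            lat = _parse_coord(row.get(lat_col), -90.0, 90.0)
            lon = _parse_coord(row.get(lon_col), -180.0, 180.0)
            if not species or lat is None or lon is None:
                n_dropped += 1
                continue
            records.append(OccurrenceRecord(species, lat, lon))

    if n_dropped:
        logger.info("dropped %d malformed row(s) while reading %s", n_dropped, path)
    if not records:
        raise EmptyInputError(f"no valid occurrence rows in {path}")
    return ReadResult(tuple(records), n_dropped)


def filter_by_bbox(
    records: Iterable[OccurrenceRecord],
    filters: Sequence[BoundingBoxFilter],
) -> list[OccurrenceRecord]:
    """Keep records inside their species' box; unfiltered species pass through."""
    by_species = {f.species: f for f in filters}
    kept = []
    for rec in records:
        box = by_species.get(rec.species)
        if box is None or box.contains(rec.latitude, rec.longitude):
            kept.append(rec)
    return kept


def read_bbox_filters(path: str | Path) -> list[BoundingBoxFilter]:
    """Read a CSV of boxes: species,min_lat,max_lat,min_lon,max_lon."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"bounding-box file not found: {path}")
    filters = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        needed = {"species", "min_lat", "max_lat", "min_lon", "max_lon"}
        if reader.fieldnames is None or needed.difference(reader.fieldnames):
            raise FormatError(f"{path} must have columns {sorted(needed)}")
        for row in reader:
            filters.append(
                BoundingBoxFilter(
                    species=row["species"].strip(),
                    min_lat=float(row["min_lat"]),
                    max_lat=float(row["max_lat"]),
                    min_lon=float(row["min_lon"]),
                    max_lon=float(row["max_lon"]),
                )
            )
    return filters


def dedupe_records(records: Iterable[OccurrenceRecord]) -> list[OccurrenceRecord]:
    """Collapse records with identical (species, lat, lon), keeping first seen."""
    seen = set()
    out = []
    for rec in records:
        key = (rec.species, rec.latitude, rec.longitude)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def write_transactions(transactions, path: str | Path) -> Path:
    """Write one comma-joined, lexicographically sorted transaction per line.

    Duplicate transactions are preserved (multiset semantics); an empty
    transaction list produces an empty, header-free file.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for t in transactions:
            sset = t.species_set if hasattr(t, "species_set") else t
            fh.write(",".join(sorted(sset)) + "\n")
    return path


def read_transactions(path: str | Path) -> list[frozenset[str]]:
    """Re-parse a transactions file back into species sets (round trip)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"transactions file not found: {path}")
    out = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(frozenset(line.split(",")))
    return out


def write_rules(
    rules,
    path: str | Path,
    subset: Literal["all", "positive", "negative"] = "all",
) -> Path:
    """Write labeled rules as TSV with a header, optionally filtered by label."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(RULE_HEADER)
        for rule in rules:
            if subset != "all" and rule.label != subset:
                continue
            writer.writerow(
                [
                    ",".join(sorted(rule.antecedent)),
                    ",".join(sorted(rule.consequent)),
                    f"{rule.support:.6g}",
                    f"{rule.confidence:.6g}",
                    f"{rule.lift:.6g}",
                    f"{rule.chi2:.6g}",
                    f"{rule.p_value:.6g}",
                    rule.label,
                ]
            )
    return path
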