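"""Synthetic multi-species occurrence patterns with planted co-occurrence.

The generator emulates the structure that drives distance-based
co-occurrence mining: groups of species sampled around shared cluster
centers (planted positive associations) and background species scattered
uniformly in a bounding box (no planted structure). Within-cluster scatter
is isotropic Gaussian in metres, mapped to degrees in a local
equirectangular tangent plane — adequate at the kilometre scales of
interest and far from the poles.

The planted truth is derived deterministically from the specification:
species sharing a group are expected to yield positive rules; pairs from
different groups whose closest cluster centers are farther apart than the
analysis distance plus six jitter standard deviations, and any pair
involving a background species, are expected non-associated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .io import OccurrenceRecord
from .spatial import haversine_distance

METERS_PER_DEGREE_LAT = 111_195.0  # pi * 6_371_000 / 180


@dataclass(frozen=True)
class SpeciesGroup:
    """Species intended to co-occur, sampled around shared centers."""

    species: tuple[str, ...]
    centers: tuple[tuple[float, float], ...]  # (lat, lon) per cluster
    points_per_species_per_cluster: int


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a synthetic occurrence dataset.

    ``jitter_m`` is the isotropic within-cluster standard deviation in
    metres. ``background`` maps species labels to uniform point counts in
    ``background_bbox`` (min_lat, max_lat, min_lon, max_lon).
    ``truth_distance_m`` is the analysis distance used to derive which
    cross-group pairs count as planted non-associations.
    """

    groups: tuple[SpeciesGroup, ...] = ()
    jitter_m: float = 200.0
    background: dict[str, int] = field(default_factory=dict)
    background_bbox: tuple[float, float, float, float] = (20.0, 25.0, 20.0, 25.0)
    seed: int = 0
    truth_distance_m: float = 5_000.0

    def validate(self) -> None:
        if self.jitter_m < 0:
            raise ConfigError(f"jitter must be >= 0, got {self.jitter_m}")
        if self.truth_distance_m <= 0:
            raise ConfigError("truth_distance_m must be positive")
        group_labels: set[str] = set()
        for g in self.groups:
            if g.points_per_species_per_cluster < 0:
                raise ConfigError("points per species per cluster must be >= 0")
            group_labels.update(g.species)
        overlap = group_labels & set(self.background)
        if overlap:
            raise ConfigError(
                f"species cannot be both grouped and background: {sorted(overlap)}"
            )
        if any(n < 0 for n in self.background.values()):
            raise ConfigError("background point counts must be >= 0")
        lo_lat, hi_lat, lo_lon, hi_lon = self.background_bbox
        if lo_lat > hi_lat or lo_lon > hi_lon:
            raise ConfigError("background bbox has min > max")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for recovery scoring, derived from a SimulationSpec."""

    expected_positive: frozenset[frozenset[str]]
    expected_non_associated: frozenset[frozenset[str]]


@dataclass(frozen=True)
class RecoveryResult:
    sensitivity: float
    false_positives: int


def planted_truth(spec: SimulationSpec) -> PlantedTruth:
    """Derive expected positive and non-associated pairs from the spec."""
    positive: set[frozenset[str]] = set()
    for g in spec.groups:
        for i, a in enumerate(g.species):
            for b in g.species[i + 1:]:
                positive.add(frozenset((a, b)))

    margin = spec.truth_distance_m + 6.0 * spec.jitter_m
    non_assoc: set[frozenset[str]] = set()
    for gi, ga in enumerate(spec.groups):
        for gb in spec.groups[gi + 1:]:
            min_d = min(
                haversine_distance(ca, cb) for ca in ga.centers for cb in gb.centers
            )
            if min_d > margin:
                for a in ga.species:
                    for b in gb.species:
                        non_assoc.add(frozenset((a, b)))
    # background species carry no planted structure with anything
    all_labels = {sp for g in spec.groups for sp in g.species} | set(spec.background)
    for bg in spec.background:
        for other in all_labels:
            if other != bg:
                non_assoc.add(frozenset((bg, other)))
    return PlantedTruth(frozenset(positive), frozenset(non_assoc - positive))


def generate_occurrences(
    spec: SimulationSpec,
) -> tuple[list[OccurrenceRecord], PlantedTruth]:
    """Sample a reproducible occurrence dataset and its planted truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[OccurrenceRecord] = []

    for g in spec.groups:
        for lat_c, lon_c in g.centers:
            for sp in g.species:
                n = g.points_per_species_per_cluster
                dy = rng.normal(0.0, spec.jitter_m, size=n)
                dx = rng.normal(0.0, spec.jitter_m, size=n)
                lat = lat_c + dy / METERS_PER_DEGREE_LAT
                lon = lon_c + dx / (
                    METERS_PER_DEGREE_LAT * np.cos(np.radians(lat_c))
                )
                records.extend(
                    OccurrenceRecord(sp, float(la), float(lo))
                    for la, lo in zip(lat, lon)
                )

    lo_lat, hi_lat, lo_lon, hi_lon = spec.background_bbox
    for sp in sorted(spec.background):
        n = spec.background[sp]
        lat = rng.uniform(lo_lat, hi_lat, size=n)
        lon = rng.uniform(lo_lon, hi_lon, size=n)
        records.extend(
            OccurrenceRecord(sp, float(la), float(lo)) for la, lo in zip(lat, lon)
        )

    return records, planted_truth(spec)


def evaluate_recovery(truth: PlantedTruth, rules: Sequence) -> RecoveryResult:
    """Score labeled rules against the planted truth.

    A planted positive pair is recovered if some positive rule's combined
    species set contains it (either rule direction). A positive rule is a
    false positive if its combined set contains any expected non-associated
    pair.
    """
    positive_rules = [r for r in rules if getattr(r, "label", None) == "positive"]
    rule_itemsets = [r.antecedent | r.consequent for r in positive_rules]

    if truth.expected_positive:
        recovered = sum(
            1
            for pair in truth.expected_positive
            if any(pair <= items for items in rule_itemsets)
        )
        sensitivity = recovered / len(truth.expected_positive)
    else:
        sensitivity = float("nan")

    fp = sum(
        1
        for items in rule_itemsets
        if any(pair <= items for pair in truth.expected_non_associated)
    )
    return RecoveryResult(sensitivity, fp)


def spec_from_json(path: str | Path) -> SimulationSpec:
    """Load a SimulationSpec from a JSON file (CLI `simulate --spec`)."""
    with Path(path).open(encoding="utf-8") as fh:
        raw = json.load(fh)
    try:
        groups = tuple(
            SpeciesGroup(
                species=tuple(g["species"]),
                centers=tuple((float(c[0]), float(c[1])) for c in g["centers"]),
                points_per_species_per_cluster=int(g["points_per_species_per_cluster"]),
            )
            for g in raw.get("groups", [])
        )
        spec = SimulationSpec(
            groups=groups,
            jitter_m=float(raw.get("jitter_m", 200.0)),
            background={str(k): int(v) for k, v in raw.get("background", {}).items()},
            background_bbox=tuple(raw.get("background_bbox", (20.0, 25.0, 20.0, 25.0))),
            seed=int(raw.get("seed", 0)),
            truth_distance_m=float(raw.get("truth_distance_m", 5_000.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulation spec {path}: {exc}") from exc
    spec.validate()
    return spec


def truth_to_json(truth: PlantedTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "expected_positive": sorted(sorted(p) for p in truth.expected_positive),
        "expected_non_associated": sorted(
            sorted(p) for p in truth.expected_non_associated
        ),
    }
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return path
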