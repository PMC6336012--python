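"""End-to-end orchestration: records -> transactions -> itemsets -> rules -> files.

A run reads an occurrence table, optionally filters by native-range
bounding boxes, builds distance transactions, mines frequent itemsets,
generates/scores/classifies association rules and writes four artifacts
into an output folder (default ``DE_results``):

    transactions.csv     one comma-joined transaction per line
    all_rules.txt        every emitted rule (TSV)
    positive_rules.txt   rules labeled positive
    negative_rules.txt   rules labeled negative

Runs are deterministic: identical input and configuration produce
byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io as oio
from .apriori import FrequentItemset, find_frequent_itemsets
from .errors import ConfigError, EmptyInputError
from .io import OccurrenceRecord
from .rules import (
    AssociationRule,
    RuleThresholds,
    generate_candidate_rules,
    score_and_classify,
    summarize_rules,
)
from .spatial import (
    Transaction,
    TransactionPolicy,
    build_transactions,
    count_unique_transactions,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    input_path: str | Path
    distance_m: float
    dialect: str = "plain"
    thresholds: RuleThresholds = field(default_factory=RuleThresholds)
    policy: TransactionPolicy = "neighborhood"
    outdir: str | Path = "DE_results"
    bbox_path: str | Path | None = None
    dedupe: bool = False
    force: bool = False

    def validate(self) -> None:
        if self.distance_m <= 0:
            raise ConfigError(f"distance must be positive, got {self.distance_m}")
        if self.policy not in ("neighborhood", "pair"):
            raise ConfigError(f"unknown transaction policy {self.policy!r}")
        if self.dialect not in oio.DIALECT_COLUMNS:
            raise ConfigError(f"unknown dialect {self.dialect!r}")


@dataclass(frozen=True)
class RunResult:
    total_transactions: int
    unique_transactions: int
    n_rules: int
    n_positive: int
    n_negative: int
    n_independent: int
    n_negligible: int
    paths: dict[str, Path]
    rules: tuple[AssociationRule, ...]
    summaries: dict[str, pd.DataFrame]


def analyze_records(
    records: Sequence[OccurrenceRecord],
    distance_m: float,
    thresholds: RuleThresholds = RuleThresholds(),
    policy: TransactionPolicy = "neighborhood",
) -> tuple[list[Transaction], list[FrequentItemset], list[AssociationRule]]:
    """Core computation shared by the CLI, sweeps and programmatic callers.

    Returns (transactions, frequent itemsets, labeled rules); all three are
    empty when no multi-species neighborhood exists at this distance.
    """
    try:
        transactions = build_transactions(records, distance_m, policy=policy)
    except EmptyInputError:
        transactions = []
    if not transactions:
        return [], [], []
    frequent = find_frequent_itemsets(transactions, thresholds.min_support)
    candidates = generate_candidate_rules(frequent, thresholds)
    labeled = score_and_classify(candidates, transactions, thresholds)
    return transactions, frequent, labeled


def _write_outputs(
    outdir: Path,
    transactions: Sequence[Transaction],
    rules: Sequence[AssociationRule],
    force: bool,
) -> dict[str, Path]:
    if outdir.exists():
        if not force:
            raise ConfigError(
                f"output folder {outdir} already exists; pass force/--force to overwrite"
            )
    else:
        outdir.mkdir(parents=True)
    paths = {
        "transactions": oio.write_transactions(transactions, outdir / "transactions.csv"),
        "all_rules": oio.write_rules(rules, outdir / "all_rules.txt", subset="all"),
        "positive_rules": oio.write_rules(
            rules, outdir / "positive_rules.txt", subset="positive"
        ),
        "negative_rules": oio.write_rules(
            rules, outdir / "negative_rules.txt", subset="negative"
        ),
    }
    return paths


def run_on_records(
    records: Sequence[OccurrenceRecord],
    distance_m: float,
    thresholds: RuleThresholds = RuleThresholds(),
    policy: TransactionPolicy = "neighborhood",
    outdir: str | Path | None = None,
    force: bool = False,
) -> RunResult:
    """Run the analysis on in-memory records, optionally writing artifacts."""
    transactions, frequent, labeled = analyze_records(
        records, distance_m, thresholds, policy
    )
    total, unique = count_unique_transactions(transactions)
    tallies = {label: 0 for label in ("positive", "negative", "independent", "negligible")}
    for rule in labeled:
        tallies[rule.label] += 1
    logger.info(
        "distance %.0f m: %d transactions (%d unique), %d frequent itemsets, "
        "%d rules (%d positive, %d negative)",
        distance_m, total, unique, len(frequent), len(labeled),
        tallies["positive"], tallies["negative"],
    )

    paths: dict[str, Path] = {}
    if outdir is not None:
        paths = _write_outputs(Path(outdir), transactions, labeled, force)

    return RunResult(
        total_transactions=total,
        unique_transactions=unique,
        n_rules=len(labeled),
        n_positive=tallies["positive"],
        n_negative=tallies["negative"],
        n_independent=tallies["independent"],
        n_negligible=tallies["negligible"],
        paths=paths,
        rules=tuple(labeled),
        summaries=summarize_rules(labeled, transactions),
    )


def load_records(config: RunConfig) -> list[OccurrenceRecord]:
    """Read, bbox-filter and optionally dedupe the configured input."""
    result = oio.read_occurrences(config.input_path, dialect=config.dialect)
    records = list(result.records)
    if config.bbox_path is not None:
        filters = oio.read_bbox_filters(config.bbox_path)
        before = len(records)
        records = oio.filter_by_bbox(records, filters)
        logger.info("bbox filters dropped %d record(s)", before - len(records))
    if config.dedupe:
        before = len(records)
        records = oio.dedupe_records(records)
        logger.info("deduplication collapsed %d record(s)", before - len(records))
    return records


def run_pipeline(config: RunConfig) -> RunResult:
    """Full file-to-files run; creates the output folder and four artifacts."""
    config.validate()
    records = load_records(config)
    return run_on_records(
        records,
        config.distance_m,
        thresholds=config.thresholds,
        policy=config.policy,
        outdir=config.outdir,
        force=config.force,
    )


def sweep_distances(
    config: RunConfig, distances_m: Sequence[float]
) -> pd.DataFrame:
    """One run per distance on the same records; rows mirror the run counts.

    Output artifacts are written into ``<outdir>/d_<metres>`` per distance.
    Returns a table with columns distance_m, total_transactions,
    unique_transactions, all_rules, positive_rules, negative_rules.
    """
    if not distances_m:
        raise ConfigError("sweep requires at least one distance")
    config.validate()
    records = load_records(config)
    rows = []
    base = Path(config.outdir)
    for d in distances_m:
        if d <= 0:
            raise ConfigError(f"distance must be positive, got {d}")
        result = run_on_records(
            records,
            d,
            thresholds=config.thresholds,
            policy=config.policy,
            outdir=base / f"d_{int(round(d))}",
            force=config.force,
        )
        rows.append(
            {
                "distance_m": d,
                "total_transactions": result.total_transactions,
                "unique_transactions": result.unique_transactions,
                "all_rules": result.n_rules,
                "positive_rules": result.n_positive,
                "negative_rules": result.n_negative,
            }
        )
    return pd.DataFrame(rows)
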