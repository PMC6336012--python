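import random

import pytest

from cooccur import OccurrenceRecord, SimulationSpec, SpeciesGroup


def recovery_spec(seed: int = 11) -> SimulationSpec:
    """The canonical recovery scenario: two planted pairs at centers ~1,000 km
    apart (each pair shares its cluster, so both should be recovered and each
    also guarantees transactions lacking the other pair — non-degenerate
    margins), plus a distant uniform background pair with no structure."""
    return SimulationSpec(
        groups=(
            SpeciesGroup(("A", "B"), ((45.0, 5.0),), 40),
            SpeciesGroup(("C", "D"), ((36.0, -4.0),), 40),
        ),
        jitter_m=200.0,
        background={"E": 30, "F": 30},
        background_bbox=(30.0, 33.0, 20.0, 23.0),
        seed=seed,
        truth_distance_m=5_000.0,
    )


@pytest.fixture
def clustered_spec() -> SimulationSpec:
    return recovery_spec()


def random_corpus(rng: random.Random, max_species: int = 12, max_transactions: int = 60):
    """A random small transaction corpus for oracle-equivalence checks."""
    m = rng.randint(2, max_species)
    species = [f"sp{i}" for i in range(m)]
    n = rng.randint(1, max_transactions)
    corpus = []
    for _ in range(n):
        size = rng.randint(1, min(m, 5))
        corpus.append(frozenset(rng.sample(species, size)))
    return corpus


def make_records(rows) -> list[OccurrenceRecord]:
    return [OccurrenceRecord(sp, lat, lon) for sp, lat, lon in rows]
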