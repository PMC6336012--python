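# Methods

## Model and procedure

`cooccur` treats spatial co-occurrence as a frequent-pattern mining
problem over *transactions* derived from point occurrences.

**Transactions.** Under the default `neighborhood` policy, each record *i*
generates the set of species of all records strictly within distance *d*
of it (its own species included). The strict `<` comparison at the
threshold is deliberate; points exactly at the threshold are out.
Transactions with fewer than two distinct species are discarded: a lone
specimen, or one surrounded only by conspecifics, carries no co-occurrence
information, and keeping singletons would also make two-species supports
of 1.0 impossible even for perfectly coexisting pairs. The alternative
`pair` policy emits one transaction per unordered mixed-species record
pair within *d*; it is kept for comparisons with record-by-record pairwise
scans, not as the default.

Distances are Haversine great-circle distances on a sphere of radius
6,371,000 m (configurable constant; the arcsine argument is clamped into
[0, 1] so antipodal rounding cannot produce NaN). No ellipsoidal geodesic
or projected CRS is attempted — occurrence coordinates are noisier than
the sphere/ellipsoid difference at the kilometre scales analysed.
Neighbor search uses a scikit-learn BallTree with the haversine metric for
more than 300 records; because the tree's candidates are re-filtered with
the package's own Haversine, the indexed and brute-force O(n²) paths
produce identical transactions (asserted in tests up to 2,000 records).

**Mining.** Apriori with apriori-gen candidate generation: frequent
k-itemsets sorted lexicographically are joined on their first k−1 items
and candidates with any infrequent k-subset are pruned. The support cut is
inclusive (≥ `min_support`, default 0.15), with a `strict` switch.
Corpora in this domain collapse to at most a few hundred distinct species
sets, so no transaction-reduction or hashing optimisations are used.

**Rules.** Every frequent itemset of size ≥ 2 is split into all
antecedent/consequent partitions; rules below `min_confidence` (default
0.3) are dropped at generation. Confidence follows the standard convention
conf(A → C) = supp(A ∪ C)/supp(A) = P(C | A) — the only convention
consistent with the identity confidence · supp(antecedent) = supp(rule),
which the test suite asserts to 1e-12. Multi-species sides are scored as
single presence/absence events (set containment), which is what rules with
three or more species require.

**Independence testing and classification.** Each rule's sides define a
2×2 table (n₁₁ both present, n₁₀ antecedent only, n₀₁ consequent only,
n₀₀ neither). Two statistics are computed:

* Pearson chi-square, df = 1, no continuity correction — reported in the
  rule files for every rule;
* the one-sided hypergeometric upper tail P(X ≥ n₁₁) with both margins
  fixed (one-sided Fisher exact test) — used for classification.

The classification criterion (positive when the p-value is ~0, negative
when ~1) is only coherent for a directional test: a two-sided statistic
cannot distinguish attraction from avoidance. Operationally, "~0" means
p ≤ α and "~1" means p ≥ 1 − α with α = 0.05 (configurable); lift
boundaries are strict (lift exactly 1 is never positive or negative).
Rules failing the support/confidence gates are negligible; those passing
the gates with neither tail fired are independent. Degenerate tables — any
zero row or column margin, typically a species present in every
transaction — return (chi² = 0, p = 1). This convention matters: a
two-species dataset where the pair always co-occurs has support,
confidence and lift all at their maxima but offers no contrast against
independence, and is correctly reported with zero positive rules. No
multiple-testing correction is applied by default (a Bonferroni option
divides α by the number of candidate rules).

## Synthetic data and what it does (not) show

The generator places groups of species around shared cluster centers with
isotropic Gaussian jitter (standard deviation in metres, mapped to degrees
in a local equirectangular tangent plane — 1/111,195 degrees per metre of
latitude, scaled by cos(lat) in longitude; adequate below ~100 km and away
from poles and antimeridian, which the defaults avoid). Background species
are uniform in a bounding box. Planted truth is derived from the spec
alone: same-group pairs are expected positive; cross-group pairs whose
closest centers are farther apart than the analysis distance plus six
jitter standard deviations, and every pair involving a background species,
are expected non-associated; nearby cross-group pairs are left
undetermined and not scored.

The canonical recovery scenario uses **two** planted pairs at centers
~1,000 km apart (40 points per species per cluster, jitter 200 m, analysis
distance 5 km) plus a distant uniform background pair (30 points each).
Two groups rather than one is a structural requirement, not a tuning
choice: with a single planted pair every transaction contains both
species, the 2×2 margins are degenerate, and under the convention above
the rule can never be positive — each group's transactions provide the
contrast that makes the other group's association testable. At these
conditions the pipeline recovers both planted pairs with sensitivity 1.0
and zero false positives across seeds; recovery scoring counts a planted
pair as found if any positive rule's combined species set contains it, and
counts a positive rule as a false positive if its combined set contains
any expected non-associated pair.

Synthetic patterns emulate clustered co-occurrence and disjoint ranges but
not the features of real occurrence data that most distort mining:
enormously unbalanced record counts between species, spatial sampling bias
toward roads and herbaria, duplicated records, and coordinate rounding.
Passing the planted-recovery tests therefore demonstrates algorithmic
correctness, not robustness to survey bias. Duplicate records are kept by
default (a `--dedupe` flag collapses exact duplicates) since the upstream
curation of real datasets is usually unknown.

## Parameters

| parameter | default | meaning |
|---|---|---|
| distance *d* | — (1–20 km typical) | neighborhood radius, metres |
| `min_support` | 0.15 | itemset frequency gate, fraction of transactions |
| `min_confidence` | 0.3 | rule emission gate, P(consequent \| antecedent) |
| lift boundaries | 1 (strict) | positive region lift > 1, negative lift < 1 |
| `alpha` | 0.05 | directional p-value cut for "~0" / "~1" |
| Earth radius | 6,371,000 m | Haversine sphere |
| jitter | 200 m | synthetic within-cluster scatter (σ) |

## Numerical and design notes

* Species labels are whitespace-trimmed, compared case-sensitively;
  transaction serialisation is lexicographically sorted and comma-joined,
  so unique-transaction counts are order-insensitive by construction.
* Bounding boxes are the only native-range filter (inclusive bounds, no
  longitude wrap-around); polygon filtering is out of scope.
* Support/confidence thresholds use exact float comparison; the supports
  involved are small-denominator rationals, so ties at the threshold are
  real and resolved inclusively.
* The pipeline is deterministic: identical input and configuration give
  byte-identical output files. The output folder (default `DE_results`,
  containing `transactions.csv`, `all_rules.txt`, `positive_rules.txt`,
  `negative_rules.txt`) is never silently overwritten without `--force`.
* Validation problem sizes: oracle equivalence uses 200 random corpora of
  ≤ 12 species and ≤ 60 transactions against exhaustive enumeration of all
  2^m − 1 itemsets; the exact test is checked against direct
  hypergeometric summation over every fixed-margin 2×2 table with N ≤ 30;
  recovery uses 20 simulated datasets of 220 records each. These sizes
  exercise every code path while keeping the whole validation suite under
  a minute.

## Known limitations

* Longitude wrap-around and polar neighborhoods are unsupported (both
  filtering and jitter mapping assume mid-latitudes).
* The focal-record transaction definition double-counts dense clusters:
  k mutually-close records generate k near-identical transactions, so
  supports reflect record density, not site counts.
* Rule counts are sensitive to `min_support` interacting with species
  record-count imbalance: an abundant species can crowd rarer ones below
  the gate.
* No correction for spatial autocorrelation: the exact test treats
  transactions as independent draws, which overlapping neighborhoods
  violate; p-values are therefore anti-conservative on dense data and the
  labels should be read as a screening heuristic, not inference.
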