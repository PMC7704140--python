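# Methods

## Data model

The corpus is 17 multi-herb bath formulas from randomized trials of
Chinese herbal bath therapy for uremic pruritus, 43 distinct herbs in
all, embedded in the package as an ordered table (`FormulaTable`): one
record per study, herbs in the originally printed order. Herb identity is
the lowercase, whitespace-trimmed pinyin token; English and Latin names
in the lexicon are display metadata only. Formulas contain no repeated
herbs, and transactions are sets, so any duplicates in external input are
collapsed (with a warning on file read).

## Transaction orientations

A formula table can be encoded as transactions two ways:

* **by_formula** — one transaction per formula (its herb set). This is
  the methodologically standard basket encoding: the support of a herb is
  the fraction of prescriptions using it, and the frequency report
  (counts per herb out of 17 formulas) is computed on this view.
* **by_rank** — lay the table out as a grid with one column per formula
  and one row per within-formula position, then take each **row** as a
  transaction: transaction r is the set of r-th herbs over all formulas
  with at least r herbs. The transaction count is the longest formula's
  length — 22 here.

The published rule table can only have come from the by_rank encoding:
every printed support and expected confidence is an integer multiple of
1/22 (e.g. 0.13636364 = 3/22), not 1/17, and re-mining the by_rank
transactions at the stated thresholds reproduces all 19 printed rules and
every metric, while by_formula mining contradicts the printed table (the
jixueteng → danggui confidence is below 1 there: danggui is missing from
one of the five jixueteng formulas). What a by_rank rule measures is
positional co-occurrence — herbs listed at the same depth across
formulas — which is how prescriptions ordered by convention (chief herbs
first) align, but it is not prescription-level co-occurrence. The package
therefore exposes both encodings, uses by_rank only in replication mode,
and records the orientation on every database.

A related consequence of set semantics: several formulas place the same
herb at the same rank, so the 182 herb placements collapse to 90 distinct
rank-herb memberships across the 22 transactions. Supports are unaffected
(a transaction either contains a herb or not), but per-rank multiplicity
is not representable, and no metric here depends on it.

## Mining

`mine_frequent` is a textbook level-wise Apriori: frequent 1-itemsets by
direct counting; candidates of size k from joining frequent (k−1)-sets
sharing a (k−2)-prefix in lexicographic order; downward-closure pruning
before counting; exact subset-scan counts. Supports are never accumulated
in floating point — each itemset carries its integer transaction count,
and proportions are formed only at the end. The frequency threshold is
inclusive, tested as `count ≥ min_support · n − 1e−12` so that exact
boundary cases (2 of 22 against 0.05, or 1 of 20 against 0.05) resolve by
arithmetic rather than float rounding. Output order is fully specified
(size, then support descending, then items lexicographic), so exports are
byte-stable. No bitmap/hash-tree acceleration: the design envelope is a
few thousand transactions, where the naive scan is instant.

`brute_force_frequent` is the verification oracle: direct enumeration of
every itemset up to the size cap, refusing universes above 20 items
(configurable). It shares no code path with the level-wise miner beyond
the single-itemset counter, and the test suite asserts equality of the
two on hundreds of randomized databases as well as on the corpus.

## Rules

Rules are generated by bipartitioning each frequent itemset and filtering
on support and confidence, with optional exact size constraints on each
side. All four metrics derive from the three integer counts (joint,
antecedent, consequent) and n; lift is computed as
`joint·n / (ante·cons)` so the identity `lift × expected confidence =
confidence` holds to 1e−12. Replication mode fixes antecedent and
consequent size to 1: all 19 published rules are 1 → 1, and without the
cap the same thresholds admit additional multi-antecedent rules the
published table does not contain, so the cap is the minimal assumption
that reproduces the published count. Sorting is support desc, confidence
desc, lift desc, then antecedent/consequent lexicographic — a total order,
hence deterministic output.

Two cells of the published expected-confidence column read 0.318181833
and 0.136363643 where the exact fractions are 7/22 = 0.3181818… and
3/22 = 0.1363636…; these are treated as printing artifacts and compared
at 1e−4 (all other metric comparisons use 1e−6).

The published narrative also highlights two-herb combinations
{chuanxiong, baijili} → {dahuang} and {dahuang, baijili} → {chuanxiong}
selected interactively from the grouping plot. Under the replication
encoding {chuanxiong, baijili} co-occur in only 1 of 22 transactions —
below minimum support — so these are presentation-layer selections, not
minable rules at the stated thresholds, and the package does not emit
them.

## Grouping

"Clusters" in the grouped-rule view are exact-antecedent groups: the 19
replication rules have exactly 9 distinct single-herb antecedents, which
reproduces the published 9-cluster layout without any heuristic (k-means
style) clustering of binarized rule sides. Group aggregates are
arithmetic means of member support and lift; groups sort by aggregate
support descending, key ascending. Scatter points are one (support,
confidence, lift) triple per rule, order preserved.

## Synthetic generator

The generator emulates sparse categorical transaction data: each
transaction includes each planted itemset wholesale with its inclusion
probability (one Bernoulli draw per pattern), plus each noise item
independently with the noise probability. Defaults — 1000 transactions,
one planted 3-itemset at inclusion 0.3, 10 noise items at 0.05 — give a
mid-sized benchmark where the planted support is far above the noise
floor. Randomness comes from `numpy.random.default_rng(seed)`; the same
spec and seed reproduce the database bit-for-bit. Empty transactions are
retained (they legitimately dilute supports) and flagged in the ground
truth.

Recovery is judged against **realized** supports, not nominal
probabilities: a planted pattern whose realized support clears the
threshold must appear in the mined output with exactly its realized
count. This makes recovery tests exact rather than statistical. What the
generator does not emulate: inter-pattern correlation beyond item
overlap, transaction-length heterogeneity, or any generative model of the
real corpus — so passing recovery tests demonstrates correctness of the
miner, not realism of the data.

## Problem sizes and numerical choices

The corpus analysis is desk-scale (22 transactions, 43 items, itemsets
capped at size 2) and runs in milliseconds. Randomized oracle-equivalence
tests use databases with up to 12 items and 30 transactions, 200
examples, derandomized for reproducibility; synthetic recovery tests use
500–1000 transactions. Thresholds in the package default to the case
study's minimum support 0.05 and minimum confidence 0.9.

## Limitations

* The by_rank encoding is reverse-engineered from the printed
  denominators; the original analysis never states its transaction unit.
  The arithmetic admits no other reading, but conclusions drawn from
  by_rank rules concern positional convention as much as co-prescription.
* With n = 22 transactions, supports are coarse (multiples of 1/22) and
  no significance testing is meaningful (none is attempted; the rule set
  carries no inferential weight).
* The miner is in-memory and unoptimized by design; it is not intended
  for datasets beyond ~10^4 transactions or dense universes where
  candidate explosion sets in.
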