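"""Synthetic transaction databases with planted co-occurring itemsets.

The generator emulates sparse categorical transaction data of the kind the
miner is meant for: a handful of "pattern" itemsets that tend to co-occur
as blocks, diluted by independent noise items. Each transaction is built by
one Bernoulli draw per planted pattern (include the whole itemset or none
of it) and one draw per noise item. Realized pattern counts are recorded as
ground truth so mining recovery can be checked exactly, with no statistical
flakiness: recovery is judged against realized supports, not nominal
probabilities.

Defaults describe a mid-sized benchmark: 1000 transactions, one planted
3-itemset included with probability 0.3, and 10 noise items each present
independently with probability 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .apriori import MiningParams, mine_frequent, support_count
from .errors import InvalidSpecError
from .transactions import Itemset, Orientation, TransactionDB

DEFAULT_PATTERNS: tuple[tuple[frozenset[str], float], ...] = (
    (frozenset({"herb_a", "herb_b", "herb_c"}), 0.3),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-pattern transaction generator.

    ``planted_patterns`` is a list of (itemset, inclusion probability)
    pairs; ``n_noise_items`` independent noise items named ``noise_000`` ...
    each enter every transaction with probability ``noise_prob``. Pattern
    item names must not collide with the noise namespace. Patterns may
    share items; inclusion draws are independent per pattern, which raises
    the expected support of overlapping unions above the product of the
    marginal probabilities.
    """

    n_transactions: int = 1000
    n_noise_items: int = 10
    noise_prob: float = 0.05
    planted_patterns: tuple[tuple[Itemset, float], ...] = DEFAULT_PATTERNS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transactions < 1:
            raise InvalidSpecError("n_transactions must be positive")
        if self.n_noise_items < 0:
            raise InvalidSpecError("n_noise_items must be nonnegative")
        if not 0.0 <= self.noise_prob <= 1.0:
            raise InvalidSpecError("noise_prob must be in [0, 1]")
        for items, prob in self.planted_patterns:
            if not items:
                raise InvalidSpecError("planted itemsets must be nonempty")
            if not 0.0 <= prob <= 1.0:
                raise InvalidSpecError("inclusion probabilities must be in [0, 1]")
            if any(i.startswith("noise_") for i in items):
                raise InvalidSpecError(
                    "planted items must not use the noise_ namespace"
                )
        if not self.planted_patterns and (
            self.n_noise_items == 0 or self.noise_prob == 0.0
        ):
            raise InvalidSpecError("spec can never produce any item")

    @property
    def noise_items(self) -> tuple[str, ...]:
        return tuple(f"noise_{i:03d}" for i in range(self.n_noise_items))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        raw = yaml.safe_load(Path(path).read_text())
        patterns = tuple(
            (frozenset(p["items"]), float(p["prob"]))
            for p in raw.get("planted_patterns", [])
        )
        kwargs = {k: raw[k] for k in
                  ("n_transactions", "n_noise_items", "noise_prob", "seed")
                  if k in raw}
        if patterns:
            kwargs["planted_patterns"] = patterns
        return cls(**kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """Realized inclusion counts per planted pattern, plus empty-transaction
    bookkeeping. Counts refer to the pattern DRAW; the realized support of
    the pattern itemset can only be >= the draw count (noise or another
    overlapping pattern may supply the same items)."""

    pattern_draw_counts: tuple[tuple[Itemset, int], ...]
    empty_transaction_indices: tuple[int, ...] = ()


def generate(spec: SyntheticSpec) -> tuple[TransactionDB, GroundTruth]:
    """Draw a database from ``spec``. Deterministic given ``spec.seed``.

    Empty transactions are retained (they dilute all supports, as real
    all-missing records would) and their indices are flagged in the truth.
    """
    rng = np.random.default_rng(spec.seed)
    noise = spec.noise_items
    patterns = spec.planted_patterns

    pattern_hits = [
        rng.random(spec.n_transactions) < prob for _, prob in patterns
    ]
    noise_hits = (
        rng.random((spec.n_transactions, len(noise))) < spec.noise_prob
        if noise
        else None
    )

    transactions = []
    empties = []
    for t in range(spec.n_transactions):
        items: set[str] = set()
        for (pat, _), hits in zip(patterns, pattern_hits):
            if hits[t]:
                items |= pat
        if noise_hits is not None:
            items.update(n for j, n in enumerate(noise) if noise_hits[t, j])
        if not items:
            empties.append(t)
        transactions.append(frozenset(items))

    db = TransactionDB(tuple(transactions), Orientation.EXTERNAL)
    truth = GroundTruth(
        pattern_draw_counts=tuple(
            (pat, int(hits.sum()))
            for (pat, _), hits in zip(patterns, pattern_hits)
        ),
        empty_transaction_indices=tuple(empties),
    )
    return db, truth


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of checking mined output against planted ground truth."""

    recovered: tuple[tuple[Itemset, int], ...]
    below_threshold: tuple[tuple[Itemset, int], ...]
    false_positive_sets: tuple[Itemset, ...]
    all_recovered: bool


def recovery_check(
    db: TransactionDB, truth: GroundTruth, params: MiningParams
) -> RecoveryReport:
    """Mine ``db`` and verify every planted pattern whose REALIZED support
    clears the threshold appears in the output with exactly its realized
    count. Frequent sets that are neither subsets of a planted pattern nor
    single noise items are reported as noise-attributable false positives.
    """
    mined = {s.items: s.count for s in mine_frequent(db, params)}
    recovered = []
    below = []
    ok = True
    for pat, _ in truth.pattern_draw_counts:
        realized = support_count(db, pat)
        if realized >= params.min_support * db.n - 1e-12 and len(pat) <= params.max_size:
            if mined.get(pat) == realized:
                recovered.append((pat, realized))
            else:
                ok = False
        else:
            below.append((pat, realized))
    planted = [pat for pat, _ in truth.pattern_draw_counts]
    false_pos = tuple(
        items
        for items in mined
        if not any(items <= pat for pat in planted)
        and not (len(items) == 1 and next(iter(items)).startswith("noise_"))
    )
    return RecoveryReport(
        recovered=tuple(recovered),
        below_threshold=tuple(below),
        false_positive_sets=false_pos,
        all_recovered=ok,
    )
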