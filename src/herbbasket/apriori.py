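"""Level-wise Apriori frequent-itemset mining with exact integer support
counting, plus a brute-force enumeration oracle.

Support is never accumulated in floating point: each itemset carries its
exact transaction count, and the support proportion is ``count / n``. The
frequency threshold is inclusive (``support >= min_support``), tested as
``count >= min_support * n`` with a 1e-12 tolerance on the product so that
exact boundary cases (e.g. 2 of 22 transactions against a 0.05 threshold)
are not lost to float rounding.

The design envelope is small, dense databases (up to a few thousand
transactions); no bitmap or hash-tree acceleration is used, and the output
order is fully specified so results are byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

from .errors import (
    EmptyDatabaseError,
    InvalidArgumentError,
    UniverseTooLargeError,
)
from .transactions import Itemset, TransactionDB

#: absolute tolerance on count >= min_support * n comparisons
THRESHOLD_TOL = 1e-12


@dataclass(frozen=True)
class MiningParams:
    """Frequency threshold and a cap on itemset cardinality."""

    min_support: float
    max_size: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.min_support <= 1.0:
            raise InvalidArgumentError("min_support must be in (0, 1]")
        if self.max_size < 1:
            raise InvalidArgumentError("max_size must be >= 1")


@dataclass(frozen=True)
class SupportedItemset:
    """An itemset together with its exact support count in a database."""

    items: Itemset
    count: int
    n: int

    def __post_init__(self) -> None:
        if not self.items:
            raise InvalidArgumentError("itemset must be nonempty")
        if not 0 <= self.count <= self.n:
            raise InvalidArgumentError("count must lie in [0, n]")

    @property
    def support(self) -> float:
        return self.count / self.n

    def sorted_items(self) -> tuple[str, ...]:
        return tuple(sorted(self.items))


def support_count(db: TransactionDB, items: Itemset | set[str]) -> int:
    """Exact number of transactions containing every item of ``items``."""
    items = frozenset(items)
    if not items:
        raise InvalidArgumentError("itemset must be nonempty")
    return sum(1 for t in db.transactions if items <= t)


def _meets_threshold(count: int, n: int, min_support: float) -> bool:
    return count >= min_support * n - THRESHOLD_TOL


def _sort_key(s: SupportedItemset):
    return (len(s.items), -s.count, s.sorted_items())


def mine_frequent(db: TransactionDB, params: MiningParams) -> list[SupportedItemset]:
    """All itemsets of size <= ``max_size`` with support >= ``min_support``.

    Classic level-wise search: frequent 1-itemsets first, then candidates of
    size k obtained by joining frequent (k-1)-itemsets that share a (k-2)
    prefix in lexicographic order, pruned by the downward-closure property
    (any candidate with an infrequent (k-1)-subset is discarded before
    counting). Output is sorted by (size asc, support desc, items asc).
    """
    if db.n == 0:
        raise EmptyDatabaseError("cannot mine an empty database")
    n = db.n
    result: list[SupportedItemset] = []

    # level 1: direct counting over the universe
    counts: dict[Itemset, int] = {}
    for t in db.transactions:
        for item in t:
            key = frozenset((item,))
            counts[key] = counts.get(key, 0) + 1
    frequent: dict[Itemset, int] = {
        s: c for s, c in counts.items() if _meets_threshold(c, n, params.min_support)
    }
    result.extend(SupportedItemset(s, c, n) for s, c in frequent.items())

    k = 2
    while frequent and k <= params.max_size:
        prev = sorted(tuple(sorted(s)) for s in frequent)
        prev_set = set(frequent)
        candidates: list[Itemset] = []
        # prefix join: two sorted (k-1)-tuples sharing their first k-2 items
        for i, a in enumerate(prev):
            for b in prev[i + 1:]:
                if a[:-1] != b[:-1]:
                    break
                cand = frozenset(a + (b[-1],))
                # downward-closure pruning before counting
                if all(cand - {x} in prev_set for x in cand):
                    candidates.append(cand)
        frequent = {}
        for cand in candidates:
            c = support_count(db, cand)
            if _meets_threshold(c, n, params.min_support):
                frequent[cand] = c
        result.extend(SupportedItemset(s, c, n) for s, c in frequent.items())
        k += 1

    result.sort(key=_sort_key)
    return result


def brute_force_frequent(
    db: TransactionDB, params: MiningParams, universe_cap: int = 20
) -> list[SupportedItemset]:
    """Testing oracle: enumerate every nonempty itemset up to ``max_size`` by
    direct subset scan. Refuses universes larger than ``universe_cap``.

    Same output contract as :func:`mine_frequent`; kept deliberately naive
    and independent of the level-wise code path.
    """
    if db.n == 0:
        raise EmptyDatabaseError("cannot mine an empty database")
    universe = sorted(db.universe)
    if len(universe) > universe_cap:
        raise UniverseTooLargeError(
            f"universe of {len(universe)} items exceeds cap {universe_cap}"
        )
    out: list[SupportedItemset] = []
    for size in range(1, min(params.max_size, len(universe)) + 1):
        for combo in combinations(universe, size):
            items = frozenset(combo)
            c = support_count(db, items)
            if _meets_threshold(c, db.n, params.min_support):
                out.append(SupportedItemset(items, c, db.n))
    out.sort(key=_sort_key)
    return out


def write_frequent_tsv(itemsets: list[SupportedItemset], path: str | Path) -> None:
    """Export frequent itemsets as TSV: items (semicolon-joined), count,
    support to 10 decimal places."""
    with Path(path).open("w") as fh:
        fh.write("items\tcount\tsupport\n")
        for s in itemsets:
            fh.write(f"{';'.join(s.sorted_items())}\t{s.count}\t{s.support:.10f}\n")
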