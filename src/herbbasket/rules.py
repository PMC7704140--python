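"""Association-rule generation and the four standard rule metrics.

For a rule A -> B over a database of n transactions:

* support            = count(A ∪ B) / n
* confidence         = count(A ∪ B) / count(A)
* expected confidence = count(B) / n  (the consequent's baseline frequency)
* lift               = confidence / expected confidence

Lift is 1 when A and B occur independently and is symmetric in A and B.
All four metrics are derived from exact integer counts.

:func:`replicate_paper_rules` runs the end-to-end published analysis on the
built-in corpus: rank-transposed transactions, frequent itemsets at minimum
support 5%, single-antecedent single-consequent rules at minimum confidence
90%, sorted by descending support — yielding the 19 published rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .apriori import MiningParams, SupportedItemset, mine_frequent, support_count
from .errors import (
    InvalidArgumentError,
    InvalidRuleError,
    UndefinedConfidenceError,
)
from .transactions import (
    Itemset,
    Orientation,
    TransactionDB,
    builtin_paper_formulas,
    to_transactions,
)


@dataclass(frozen=True)
class AssociationRule:
    """A -> B with its four metrics and the exact counts behind them."""

    antecedent: Itemset
    consequent: Itemset
    joint_count: int
    antecedent_count: int
    consequent_count: int
    n: int

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise InvalidRuleError("antecedent and consequent must be nonempty")
        if self.antecedent & self.consequent:
            raise InvalidRuleError("antecedent and consequent must be disjoint")
        if self.antecedent_count == 0:
            raise UndefinedConfidenceError(
                "confidence undefined: antecedent never occurs"
            )

    @property
    def support(self) -> float:
        return self.joint_count / self.n

    @property
    def confidence(self) -> float:
        return self.joint_count / self.antecedent_count

    @property
    def expected_confidence(self) -> float:
        return self.consequent_count / self.n

    @property
    def lift(self) -> float:
        # = confidence / expected_confidence, rearranged onto integers first
        return (self.joint_count * self.n) / (
            self.antecedent_count * self.consequent_count
        )

    def label(self) -> str:
        lhs = ",".join(sorted(self.antecedent))
        rhs = ",".join(sorted(self.consequent))
        return f"{{{lhs}}} => {{{rhs}}}"


@dataclass(frozen=True)
class RuleFilter:
    """Thresholds and shape constraints for rule generation.

    ``antecedent_size``/``consequent_size`` of ``None`` means unbounded; the
    published analysis is replicated with both fixed to 1.
    """

    min_support: float
    min_confidence: float
    antecedent_size: int | None = None
    consequent_size: int | None = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.min_support <= 1.0:
            raise InvalidArgumentError("min_support must be in (0, 1]")
        if not 0.0 < self.min_confidence <= 1.0:
            raise InvalidArgumentError("min_confidence must be in (0, 1]")
        for sz in (self.antecedent_size, self.consequent_size):
            if sz is not None and sz < 1:
                raise InvalidArgumentError("size constraints must be >= 1 or None")


def rule_metrics(
    db: TransactionDB, antecedent: Itemset | set[str], consequent: Itemset | set[str]
) -> AssociationRule:
    """Compute all four metrics for A -> B from exact counts on ``db``."""
    antecedent = frozenset(antecedent)
    consequent = frozenset(consequent)
    if not antecedent or not consequent:
        raise InvalidRuleError("antecedent and consequent must be nonempty")
    if antecedent & consequent:
        raise InvalidRuleError("antecedent and consequent must be disjoint")
    return AssociationRule(
        antecedent=antecedent,
        consequent=consequent,
        joint_count=support_count(db, antecedent | consequent),
        antecedent_count=support_count(db, antecedent),
        consequent_count=support_count(db, consequent),
        n=db.n,
    )


_CONF_TOL = 1e-12


def generate_rules(
    db: TransactionDB,
    frequent: list[SupportedItemset],
    rule_filter: RuleFilter,
) -> list[AssociationRule]:
    """Emit every rule splitting a frequent itemset into an antecedent and a
    consequent of the configured sizes, with support >= min_support and
    confidence >= min_confidence. Duplicate-free; output order is determined
    by :func:`sort_rules` applied at the end.
    """
    counts: dict[Itemset, int] = {s.items: s.count for s in frequent}

    def count_of(items: Itemset) -> int:
        if items in counts:
            return counts[items]
        return support_count(db, items)

    seen: set[tuple[Itemset, Itemset]] = set()
    out: list[AssociationRule] = []
    for s in frequent:
        items = s.items
        if len(items) < 2:
            continue
        if not s.count >= rule_filter.min_support * db.n - _CONF_TOL:
            continue
        sorted_items = sorted(items)
        # every proper nonempty bipartition
        for mask in range(1, 2 ** len(sorted_items) - 1):
            ante = frozenset(
                it for i, it in enumerate(sorted_items) if mask >> i & 1
            )
            cons = items - ante
            if rule_filter.antecedent_size is not None and len(ante) != rule_filter.antecedent_size:
                continue
            if rule_filter.consequent_size is not None and len(cons) != rule_filter.consequent_size:
                continue
            if (ante, cons) in seen:
                continue
            seen.add((ante, cons))
            ante_count = count_of(ante)
            if s.count < rule_filter.min_confidence * ante_count - _CONF_TOL:
                continue
            out.append(
                AssociationRule(
                    antecedent=ante,
                    consequent=cons,
                    joint_count=s.count,
                    antecedent_count=ante_count,
                    consequent_count=count_of(cons),
                    n=db.n,
                )
            )
    return sort_rules(out)


def sort_rules(rules: list[AssociationRule]) -> list[AssociationRule]:
    """Stable sort: support desc, confidence desc, lift desc, then
    antecedent and consequent lexicographic asc."""
    return sorted(
        rules,
        key=lambda r: (
            -r.support,
            -r.confidence,
            -r.lift,
            tuple(sorted(r.antecedent)),
            tuple(sorted(r.consequent)),
        ),
    )


def replicate_paper_rules() -> list[AssociationRule]:
    """End-to-end replication of the published analysis on the built-in
    corpus: by_rank transactions, min support 0.05, 1 -> 1 rules at min
    confidence 0.9, sorted by descending support. Returns 19 rules."""
    table = builtin_paper_formulas()
    db = to_transactions(table, Orientation.BY_RANK)
    frequent = mine_frequent(db, MiningParams(min_support=0.05, max_size=2))
    return generate_rules(
        db,
        frequent,
        RuleFilter(min_support=0.05, min_confidence=0.9,
                   antecedent_size=1, consequent_size=1),
    )


def write_rules_tsv(rules: list[AssociationRule], path: str | Path) -> None:
    """Rule table export: 8 decimals for support/expected confidence, 6 for
    confidence and lift (mirroring the published table's mixed precision)."""
    with Path(path).open("w") as fh:
        fh.write("no\trule\tsupport\tconfidence\texpected_confidence\tlift\n")
        for i, r in enumerate(rules, start=1):
            fh.write(
                f"{i}\t{r.label()}\t{r.support:.8f}\t{r.confidence:.6f}"
                f"\t{r.expected_confidence:.8f}\t{r.lift:.6f}\n"
            )


def write_rules_json(rules: list[AssociationRule], path: str | Path) -> None:
    """JSON export including the exact integer counts behind each metric."""
    payload = [
        {
            "antecedent": sorted(r.antecedent),
            "consequent": sorted(r.consequent),
            "joint_count": r.joint_count,
            "antecedent_count": r.antecedent_count,
            "consequent_count": r.consequent_count,
            "n": r.n,
            "support": r.support,
            "confidence": r.confidence,
            "expected_confidence": r.expected_confidence,
            "lift": r.lift,
        }
        for r in rules
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")
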