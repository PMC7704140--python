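"""Grouped-rule structure and scatter coordinates for rule visualization.

Rules are grouped by their exact antecedent itemset. On the built-in corpus
the 19 replication rules have 9 distinct single-herb antecedents, so the
grouping reproduces the published 9-cluster layout without any heuristic
clustering. Scatter points are (support, confidence) pairs with lift carried
along for coloring, one per rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .rules import AssociationRule
from .transactions import Itemset


@dataclass(frozen=True)
class RuleGroup:
    """All rules sharing one antecedent, with mean support and lift."""

    key: Itemset
    rules: tuple[AssociationRule, ...]

    @property
    def aggregate_support(self) -> float:
        return sum(r.support for r in self.rules) / len(self.rules)

    @property
    def aggregate_lift(self) -> float:
        return sum(r.lift for r in self.rules) / len(self.rules)


@dataclass(frozen=True)
class ScatterPoint:
    support: float
    confidence: float
    lift: float
    rule_index: int


def group_by_antecedent(rules: list[AssociationRule]) -> list[RuleGroup]:
    """Partition rules by exact antecedent itemset; groups sorted by
    aggregate support desc then key asc."""
    buckets: dict[Itemset, list[AssociationRule]] = {}
    for r in rules:
        buckets.setdefault(r.antecedent, []).append(r)
    groups = [RuleGroup(key, tuple(members)) for key, members in buckets.items()]
    groups.sort(key=lambda g: (-g.aggregate_support, tuple(sorted(g.key))))
    return groups


def scatter_points(rules: list[AssociationRule]) -> list[ScatterPoint]:
    """One (support, confidence, lift) point per rule, order preserved."""
    return [
        ScatterPoint(r.support, r.confidence, r.lift, i)
        for i, r in enumerate(rules)
    ]


def grouping_matrix(rules: list[AssociationRule]) -> dict:
    """Grouping-matrix layout: columns = antecedent groups, rows =
    consequent items, each cell = (n_rules, mean support, mean lift)."""
    groups = group_by_antecedent(rules)
    consequents = sorted({item for r in rules for item in r.consequent})
    columns = [";".join(sorted(g.key)) for g in groups]
    cells: dict[str, dict[str, dict]] = {}
    for g, col in zip(groups, columns):
        for cons in consequents:
            members = [r for r in g.rules if cons in r.consequent]
            if not members:
                continue
            cells.setdefault(cons, {})[col] = {
                "n_rules": len(members),
                "mean_support": sum(r.support for r in members) / len(members),
                "mean_lift": sum(r.lift for r in members) / len(members),
            }
    return {
        "columns": columns,
        "rows": consequents,
        "cells": cells,
        "n_groups": len(groups),
        "n_rules": len(rules),
    }


def write_grouping_json(rules: list[AssociationRule], path: str | Path) -> None:
    Path(path).write_text(json.dumps(grouping_matrix(rules), indent=1) + "\n")
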