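"""Herb-usage frequency distribution over formulas and summary statistics.

Frequencies are always counted on the by_formula view (one prescription, one
observation): the count of a herb is the number of formulas whose herb set
contains it, regardless of position. The report records that orientation so
downstream exports are unambiguous, since rule replication on the built-in
corpus uses the by_rank view instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .errors import InvalidArgumentError
from .transactions import FormulaTable, Lexicon, Orientation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyReport:
    """Per-herb usage counts sorted by count desc then name asc."""

    entries: tuple[tuple[str, int], ...]
    n_formulas: int
    orientation: Orientation = Orientation.BY_FORMULA

    def as_dict(self) -> dict[str, int]:
        return dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def herb_frequencies(table: FormulaTable) -> FrequencyReport:
    """Count, for every herb, the number of formulas that contain it."""
    counts: dict[str, int] = {}
    for rec in table.records:
        for herb in set(rec.herbs):
            counts[herb] = counts.get(herb, 0) + 1
    entries = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return FrequencyReport(entries, n_formulas=len(table))


def top_k(report: FrequencyReport, k: int) -> list[str]:
    """The k most-used herbs; ties broken lexicographically by pinyin.

    Asking for more entries than exist returns all of them with a warning.
    """
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if k > len(report.entries):
        logger.warning(
            "requested top %d of %d entries; returning all", k, len(report.entries)
        )
    return [name for name, _ in report.entries[:k]]


def mean_formula_size(table: FormulaTable) -> float:
    """Arithmetic mean number of herbs per formula."""
    return sum(len(r.herbs) for r in table.records) / len(table.records)


def write_frequency_tsv(
    report: FrequencyReport, path: str | Path, lexicon: Lexicon | None = None
) -> None:
    """Frequency TSV (pinyin, english, latin, count), joinable against a
    lexicon when one is given; display names are blank otherwise."""
    by_pinyin = lexicon.by_pinyin if lexicon is not None else {}
    with Path(path).open("w") as fh:
        fh.write("pinyin\tenglish\tlatin\tcount\n")
        for name, count in report.entries:
            entry = by_pinyin.get(name)
            english = entry.english_name if entry else ""
            latin = entry.latin_name if entry else ""
            fh.write(f"{name}\t{english}\t{latin}\t{count}\n")
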