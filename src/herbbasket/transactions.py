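"""Item normalization, the built-in formula corpus, and transaction databases.

A *formula* is an ordered list of herb names; a *transaction database* is a
list of item sets over which supports are counted. A formula table can be
turned into transactions in two orientations:

``by_formula``
    One transaction per formula — the conventional market-basket encoding:
    support of a herb is the fraction of prescriptions using it.

``by_rank``
    The table is laid out as a grid with one column per formula and one row
    per within-formula position (rank); each ROW becomes a transaction, so the
    number of transactions equals the longest formula's length. For the
    built-in corpus this is 22, and it is this encoding — not by_formula —
    whose supports reproduce the published rule table, every one of whose
    support values is an integer multiple of 1/22. Both encodings are exposed;
    see docs/methods.md for the full discussion of this duality.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from ._fixture import PAPER_FORMULAS, PAPER_LEXICON
from .errors import (
    EmptyDatabaseError,
    InvalidArgumentError,
    InvalidItemError,
    ParseError,
)

logger = logging.getLogger(__name__)

Itemset = frozenset[str]


def normalize_item(raw_name: str) -> str:
    """Normalize a raw item name to its canonical id (trimmed, lowercase).

    Idempotent. Raises :class:`InvalidItemError` on empty/whitespace input.
    """
    if not isinstance(raw_name, str):
        raise InvalidItemError(f"item name must be a string, got {type(raw_name).__name__}")
    token = raw_name.strip().lower()
    if not token:
        raise InvalidItemError("item name is empty after trimming")
    return token


class Orientation(str, Enum):
    """How a transaction database was derived from its source table."""

    BY_FORMULA = "by_formula"
    BY_RANK = "by_rank"
    EXTERNAL = "external"


@dataclass(frozen=True)
class HerbEntry:
    """One lexicon row: canonical pinyin id plus display names and the
    herb's usage count among the source formulas."""

    pinyin_name: str
    english_name: str
    latin_name: str
    paper_frequency: int

    def __post_init__(self) -> None:
        if self.paper_frequency < 0:
            raise InvalidArgumentError("paper_frequency must be nonnegative")


@dataclass(frozen=True)
class Lexicon:
    """Item lexicon keyed by normalized pinyin name."""

    entries: tuple[HerbEntry, ...]

    def __post_init__(self) -> None:
        names = [e.pinyin_name for e in self.entries]
        if len(set(names)) != len(names):
            raise InvalidArgumentError("duplicate pinyin names in lexicon")

    def __contains__(self, item: str) -> bool:
        return item in self.by_pinyin

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def by_pinyin(self) -> dict[str, HerbEntry]:
        return {e.pinyin_name: e for e in self.entries}


@dataclass(frozen=True)
class FormulaRecord:
    """One study's prescription: an ordered, duplicate-free herb list."""

    study_label: str
    herbs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.herbs:
            raise InvalidArgumentError(f"{self.study_label!r}: empty herb list")
        if len(set(self.herbs)) != len(self.herbs):
            raise InvalidArgumentError(f"{self.study_label!r}: duplicate herbs")


@dataclass(frozen=True)
class FormulaTable:
    """An ordered collection of formulas, optionally tied to a lexicon."""

    records: tuple[FormulaRecord, ...]
    lexicon: Lexicon | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise InvalidArgumentError("formula table has no records")
        if self.lexicon is not None:
            for rec in self.records:
                unknown = [h for h in rec.herbs if h not in self.lexicon]
                if unknown:
                    raise InvalidArgumentError(
                        f"{rec.study_label!r}: herbs not in lexicon: {unknown}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def max_len(self) -> int:
        """Length of the longest formula (the by_rank transaction count)."""
        return max(len(r.herbs) for r in self.records)

    @property
    def all_herbs(self) -> frozenset[str]:
        return frozenset(h for r in self.records for h in r.herbs)


@dataclass(frozen=True)
class TransactionDB:
    """An ordered list of item sets with a record of how it was derived."""

    transactions: tuple[Itemset, ...]
    orientation: Orientation = Orientation.EXTERNAL

    @property
    def n(self) -> int:
        return len(self.transactions)

    @property
    def universe(self) -> frozenset[str]:
        return frozenset().union(*self.transactions) if self.transactions else frozenset()

    def __len__(self) -> int:
        return len(self.transactions)

    def __iter__(self):
        return iter(self.transactions)


def builtin_paper_lexicon() -> Lexicon:
    """The 43-herb lexicon of the built-in corpus, with usage frequencies."""
    return Lexicon(tuple(HerbEntry(*row) for row in PAPER_LEXICON))


def builtin_paper_formulas() -> FormulaTable:
    """The built-in corpus: 17 published herbal-bath formulas (43 distinct
    herbs), each with its herbs in the originally printed order."""
    lex = builtin_paper_lexicon()
    records = tuple(
        FormulaRecord(label, tuple(normalize_item(h) for h in herbs))
        for label, herbs in PAPER_FORMULAS
    )
    return FormulaTable(records, lexicon=lex)


def to_transactions(
    table: FormulaTable, orientation: Orientation | str
) -> TransactionDB:
    """Encode a formula table as a transaction database.

    ``by_formula``: one transaction per record (its herb set).
    ``by_rank``: transaction r = the set of r-th herbs over all formulas of
    length >= r, for r = 1 .. max_len.
    """
    try:
        orientation = Orientation(orientation)
    except ValueError:
        raise InvalidArgumentError(f"unknown orientation: {orientation!r}") from None
    if orientation is Orientation.BY_FORMULA:
        tx = tuple(frozenset(r.herbs) for r in table.records)
    elif orientation is Orientation.BY_RANK:
        tx = tuple(
            frozenset(r.herbs[rank] for r in table.records if len(r.herbs) > rank)
            for rank in range(table.max_len)
        )
    else:
        raise InvalidArgumentError(
            "orientation must be by_formula or by_rank when deriving from a table"
        )
    return TransactionDB(tx, orientation)


def make_db(
    transactions: Iterable[Iterable[str]],
    orientation: Orientation | str = Orientation.EXTERNAL,
    normalize: bool = False,
) -> TransactionDB:
    """Build a :class:`TransactionDB` from raw iterables of items."""
    if normalize:
        tx = tuple(frozenset(normalize_item(i) for i in t) for t in transactions)
    else:
        tx = tuple(frozenset(t) for t in transactions)
    return TransactionDB(tx, Orientation(orientation))


# ---------------------------------------------------------------------------
# file I/O: basket CSV, long CSV, grid CSV, lexicon TSV


def read_basket(path: str | Path) -> TransactionDB:
    """Read a basket CSV: one transaction per line, items comma-separated.

    Items are normalized; duplicates within a line are collapsed with a
    logged warning. An empty file is an error.
    """
    path = Path(path)
    transactions: list[Itemset] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                items = [normalize_item(tok) for tok in line.split(",") if tok.strip()]
            except InvalidItemError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            if not items:
                raise ParseError("no items on line", line=lineno)
            tx = frozenset(items)
            if len(tx) < len(items):
                logger.warning(
                    "%s:%d: duplicate items collapsed (%d -> %d)",
                    path, lineno, len(items), len(tx),
                )
            transactions.append(tx)
    if not transactions:
        raise EmptyDatabaseError(f"{path}: no transactions")
    return TransactionDB(tuple(transactions), Orientation.EXTERNAL)


def write_basket(db: TransactionDB, path: str | Path) -> None:
    """Write a basket CSV; items within a transaction are sorted for
    byte-stable output. Round-trips through :func:`read_basket`."""
    if db.n == 0:
        raise EmptyDatabaseError("refusing to write an empty database")
    path = Path(path)
    with path.open("w") as fh:
        for tx in db.transactions:
            fh.write(",".join(sorted(tx)) + "\n")


def read_long(path: str | Path) -> TransactionDB:
    """Read a long-format CSV with header ``transaction_id,item``.

    Transactions appear in order of first occurrence of their id.
    """
    path = Path(path)
    groups: dict[str, set[str]] = {}
    with path.open() as fh:
        header = fh.readline()
        if not header:
            raise EmptyDatabaseError(f"{path}: empty file")
        cols = [c.strip().lower() for c in header.split(",")]
        if cols[:2] != ["transaction_id", "item"]:
            raise ParseError("expected header 'transaction_id,item'", line=1)
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"expected 2 fields, got {len(parts)}", line=lineno)
            tid, raw = parts
            try:
                item = normalize_item(raw)
            except InvalidItemError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            groups.setdefault(tid.strip(), set()).add(item)
    if not groups:
        raise EmptyDatabaseError(f"{path}: no transactions")
    return TransactionDB(
        tuple(frozenset(s) for s in groups.values()), Orientation.EXTERNAL
    )


def write_long(db: TransactionDB, path: str | Path) -> None:
    if db.n == 0:
        raise EmptyDatabaseError("refusing to write an empty database")
    with Path(path).open("w") as fh:
        fh.write("transaction_id,item\n")
        for i, tx in enumerate(db.transactions, start=1):
            for item in sorted(tx):
                fh.write(f"t{i},{item}\n")


def read_grid(path: str | Path) -> FormulaTable:
    """Read a grid CSV mirroring the published layout: one COLUMN per
    formula (header = study labels), one row per within-formula rank,
    empty cells where a formula has ended."""
    path = Path(path)
    with path.open() as fh:
        lines = [line.rstrip("\n") for line in fh]
    if not lines or not lines[0].strip():
        raise EmptyDatabaseError(f"{path}: empty grid")
    labels = [c.strip() for c in lines[0].split(",")]
    columns: list[list[str]] = [[] for _ in labels]
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) > len(labels):
            raise ParseError(
                f"row has {len(cells)} cells but header has {len(labels)}",
                line=lineno,
            )
        for j, cell in enumerate(cells):
            if cell.strip():
                try:
                    columns[j].append(normalize_item(cell))
                except InvalidItemError as exc:
                    raise ParseError(str(exc), line=lineno) from exc
    records = tuple(
        FormulaRecord(label, tuple(col))
        for label, col in zip(labels, columns)
        if col
    )
    if not records:
        raise EmptyDatabaseError(f"{path}: grid has no herbs")
    return FormulaTable(records)


def write_grid(table: FormulaTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(",".join(r.study_label.replace(",", ";") for r in table.records) + "\n")
        for rank in range(table.max_len):
            fh.write(
                ",".join(
                    r.herbs[rank] if len(r.herbs) > rank else ""
                    for r in table.records
                )
                + "\n"
            )


def read_lexicon(path: str | Path) -> Lexicon:
    """Read a lexicon TSV with columns pinyin, english, latin[, frequency]."""
    entries = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("expected at least 3 tab-separated fields", line=lineno)
            freq = int(parts[3]) if len(parts) > 3 and parts[3].strip() else 0
            entries.append(HerbEntry(normalize_item(parts[0]), parts[1], parts[2], freq))
    return Lexicon(tuple(entries))


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for e in lexicon.entries:
            fh.write(f"{e.pinyin_name}\t{e.english_name}\t{e.latin_name}\t{e.paper_frequency}\n")
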