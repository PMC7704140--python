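"""Exception hierarchy for herbbasket.

All library-raised errors derive from :class:`HerbBasketError` so callers
(and the CLI) can distinguish domain failures from programming errors.
"""


class HerbBasketError(Exception):
    """Base class for all herbbasket errors."""


class InvalidItemError(HerbBasketError):
    """An item name is empty or otherwise unusable after normalization."""


class InvalidArgumentError(HerbBasketError):
    """A structurally invalid argument (unknown orientation, bad filter ...)."""


class EmptyDatabaseError(HerbBasketError):
    """A transaction database was required to be nonempty but is not."""


class ParseError(HerbBasketError):
    """A data file could not be parsed; ``line`` carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UndefinedConfidenceError(HerbBasketError):
    """Rule confidence is undefined because the antecedent never occurs."""


class InvalidRuleError(HerbBasketError):
    """Antecedent and consequent are empty or overlap."""


class UniverseTooLargeError(HerbBasketError):
    """The brute-force oracle refused a universe above its enumeration cap."""


class InvalidSpecError(HerbBasketError):
    """A synthetic-data specification is invalid."""


class ReplicationMismatchError(HerbBasketError):
    """Recomputed results differ from the embedded published tables."""
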