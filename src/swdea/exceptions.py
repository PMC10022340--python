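"""Exception hierarchy shared across the package."""


class SWDEAError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SWDEAError):
    """A required column is missing or a column mapping is invalid."""


class IntegrityError(SWDEAError):
    """Panel integrity violated (e.g. duplicate (country, year) keys)."""


class PanelValidationError(SWDEAError):
    """One or more rows violate the panel invariants.

    Carries ``rows``: a list of (row_number, message) pairs.
    """

    def __init__(self, rows):
        self.rows = list(rows)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.rows[:10])
        more = "" if len(self.rows) <= 10 else f" (+{len(self.rows) - 10} more)"
        super().__init__(f"{len(self.rows)} invalid row(s): {lines}{more}")


class DomainError(SWDEAError):
    """An argument lies outside the mathematical domain of an operation."""


class ScoringError(SWDEAError):
    """The DEA linear program failed for a named DMU."""


class ConvergenceError(SWDEAError):
    """An iterative fit (EM, MLE) failed to converge."""


class GenerationError(SWDEAError):
    """A synthetic-data configuration produced invalid observations."""
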