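"""Exception types shared across the package."""


class DPGenomeError(Exception):
    """Base class for all package errors."""


class FormatError(DPGenomeError, ValueError):
    """A file could not be parsed (malformed cell, ragged row, bad body/metadata)."""


class ValidationError(DPGenomeError, ValueError):
    """An in-memory object violates one of its invariants."""


class CoverageError(ValidationError):
    """A taxonomy forest does not cover every block value observed in the data."""

    def __init__(self, uncovered):
        self.uncovered = list(uncovered)
        pairs = ", ".join(f"(block {b + 1}, {v!r})" for b, v in self.uncovered[:10])
        more = "" if len(self.uncovered) <= 10 else f" ... ({len(self.uncovered)} total)"
        super().__init__(f"taxonomy does not cover observed block values: {pairs}{more}")


class StateError(DPGenomeError, RuntimeError):
    """An operation was applied in an invalid state (e.g. specializing a node not in the cut)."""
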