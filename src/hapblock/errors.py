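"""Exception hierarchy for hapblock."""


class HapblockError(Exception):
    """Base class for all hapblock errors."""


class ParseError(HapblockError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class BiallelicViolationError(ParseError):
    """More than two distinct non-missing alleles observed at one locus."""


class ConfigError(HapblockError):
    """Inconsistent or impossible configuration."""


class UncoverableColumnError(HapblockError):
    """A SNP column cannot be covered by any feasible block."""

    def __init__(self, column: int):
        super().__init__(
            f"column {column} is not covered by any block with diversity "
            f"within the limit; no full segmentation exists"
        )
        self.column = column


class NoDistinguishingSetError(HapblockError):
    """No locus subset within the budget separates all haplotype groups."""


class MissingScoresError(HapblockError):
    """The merged score stream does not cover every required interval."""

    def __init__(self, detail: str):
        super().__init__(f"incomplete diversity-score coverage: {detail}")
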