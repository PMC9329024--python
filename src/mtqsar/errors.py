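"""Exception hierarchy shared across the package."""


class MtqsarError(Exception):
    """Base class for all package-specific errors."""


class InvalidSmilesError(MtqsarError):
    """A SMILES string could not be parsed into a molecule.

    Carries the offending string so batch callers can log and skip it.
    """

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        self.reason = reason
        super().__init__(f"{reason}: {smiles!r}")


class InvalidSequenceError(MtqsarError):
    """A protein sequence contains a letter outside the 20-letter alphabet."""

    def __init__(self, letter: str, position: int):
        self.letter = letter
        self.position = position
        super().__init__(
            f"non-standard amino acid {letter!r} at position {position}"
        )


class DomainError(MtqsarError):
    """A numeric argument is outside the mathematical domain of an operation."""


class ConfigError(MtqsarError):
    """A configuration file or mapping is malformed or has unknown keys."""


class UnknownTargetError(MtqsarError):
    """A query names a target that is not registered in the model suite."""

    def __init__(self, target_id: str, known: list[str]):
        self.target_id = target_id
        self.known = list(known)
        super().__init__(
            f"unknown target {target_id!r}; registered targets: {sorted(known)}"
        )


class BatchLimitError(MtqsarError):
    """A prediction batch exceeds the configured molecule cap."""

    def __init__(self, n: int, cap: int):
        self.n = n
        self.cap = cap
        super().__init__(f"batch of {n} molecules exceeds the cap of {cap}")
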