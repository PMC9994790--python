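"""Exception hierarchy shared across the package."""


class BloomsigError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BloomsigError):
    """A configuration value is missing, malformed, or infeasible."""


class SequenceParseError(BloomsigError):
    """Malformed FASTA/FASTQ input; carries the byte offset of the defect."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (byte offset {offset})")
        self.offset = offset


class StoreCorruptionError(BloomsigError):
    """An on-disk store is incomplete or inconsistent with its metadata."""


class CompatibilityError(BloomsigError):
    """Bloom parameters of two artifacts (index vs. query/update) disagree."""
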