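"""Exception types shared across the package."""


class KmerdiffError(Exception):
    """Base class for all package errors."""


class InvalidSequenceError(KmerdiffError):
    """A sequence contains characters outside the DNA alphabet."""


class FastqParseError(KmerdiffError):
    """A FASTQ file could not be parsed; message names file and record index."""


class UnsortedInputError(KmerdiffError):
    """A k-mer dump violated lexicographic ordering; message names file and line."""


class ConfigError(KmerdiffError):
    """Inconsistent or invalid configuration (e.g. k mismatch between inputs)."""
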