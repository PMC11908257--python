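"""Exception hierarchy shared across the package.

Each error class carries the process exit code used by the CLI so that
config, parse, and integrity failures are distinguishable by callers.
"""


class NrgcatError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(NrgcatError):
    """Invalid configuration, manifest field, or parameter value."""

    exit_code = 2


class ParameterError(ConfigError):
    """Out-of-range numeric parameter (subclass of config errors)."""


class ParseError(NrgcatError):
    """Malformed input file (FASTA/FASTQ/TSV/SAM)."""

    exit_code = 3


class IntegrityError(NrgcatError):
    """Cross-reference violation between artifacts (e.g. alignment to an
    NRG missing from the catalog)."""

    exit_code = 4


class SchemaError(ParseError):
    """A table is missing a required column."""
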