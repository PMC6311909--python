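"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration errors -> 2,
data-format errors -> 3, numerical/internal errors -> 4.
"""


class PftpError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PftpError):
    """Invalid hyperparameter, schedule or partition configuration."""

    exit_code = 2


class InputError(PftpError):
    """Malformed or inconsistent input data (FASTA, TSV, BoW files)."""

    exit_code = 3


class InternalError(PftpError):
    """Numerical or bookkeeping failure that indicates a bug."""

    exit_code = 4
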