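"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors -> 2, data-format
errors -> 3, numerical errors -> 4.
"""


class FragmethError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class UsageError(FragmethError):
    """Invalid invocation or inputs that cannot be analysed as requested."""

    exit_code = 2


class DataFormatError(FragmethError):
    """Malformed input file (FASTA/BAM/BED/TSV)."""

    exit_code = 3


class NumericalError(FragmethError):
    """Non-finite likelihoods, degenerate optimisation, solver failure."""

    exit_code = 4


class DegenerateModelError(NumericalError):
    """Mixture-model initialisation collapsed (e.g. an empty component)."""
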