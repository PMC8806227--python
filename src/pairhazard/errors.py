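"""Exception hierarchy shared by all pipeline stages.

The CLI maps these onto exit codes: configuration problems exit 2, data
problems exit 3, and an analysable-but-empty result ("no signal") exits 4.
"""


class PairhazardError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(PairhazardError):
    """Invalid configuration: bad parameter values, missing files, unit mismatch."""


class DataFormatError(PairhazardError):
    """A file or table violates its format contract (parse errors, bad domains)."""


class DomainError(PairhazardError):
    """Inputs are well-formed but outside an operation's mathematical domain."""


class AlignmentError(PairhazardError):
    """Two artifacts that must share identifiers (genes, samples, pairs) do not."""


class NoSignalError(PairhazardError):
    """A filtering or selection stage retained nothing; the pipeline cannot proceed."""
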