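class GatescanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GatescanError):
    """Malformed input file (FASTA/GFF3/Newick/alignment)."""


class InputError(GatescanError):
    """Arguments violate an operation's preconditions."""


class ConfigError(GatescanError):
    """Invalid or inconsistent configuration."""


class CalibrationError(GatescanError):
    """E-value calibration could not be performed (e.g. degenerate null)."""
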