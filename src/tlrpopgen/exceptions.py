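"""Exception hierarchy for the pipeline."""


class TLRPopgenError(Exception):
    """Base class for all package errors."""


class AlignmentFormatError(TLRPopgenError):
    """Malformed or inconsistent sequence input (unequal lengths, empty file)."""


class ConfigurationError(TLRPopgenError):
    """Invalid or inconsistent study configuration."""


class DegenerateAlignmentError(TLRPopgenError):
    """An operation removed every usable column of an alignment."""


class DataError(TLRPopgenError):
    """Biologically invalid data, e.g. an internal stop codon."""


class SaturationError(TLRPopgenError):
    """Divergence too large for the Jukes-Cantor correction (p >= 3/4)."""


class ModelError(TLRPopgenError):
    """Malformed demographic model (e.g. lineages cannot fully coalesce)."""


class NumericalError(TLRPopgenError):
    """A numerical fit failed to converge."""


class UsageError(TLRPopgenError):
    """An operation was called on input it is not defined for."""
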