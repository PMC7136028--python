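"""Exception hierarchy.

Every error raised by the library derives from :class:`AmplimethError` so
callers (and the CLI) can distinguish library failures from programming
errors.
"""


class AmplimethError(Exception):
    """Base class for all amplimeth errors."""


class InputError(AmplimethError, ValueError):
    """Malformed or out-of-contract input."""


class InfeasibleSequenceError(AmplimethError):
    """Requested promoter composition cannot be realised."""


class UndefinedDensityError(AmplimethError):
    """CpG density undefined (empty, all-N, or mostly-N sequence)."""


class UndefinedEfficiencyError(AmplimethError):
    """Conversion efficiency undefined: no non-CpG cytosine covered."""


class EmptyProfileError(AmplimethError):
    """No clone passed QC; methylation profile undefined."""


class AlleleMissingError(AmplimethError):
    """An allele required for an allelic comparison has no passing clones."""

    def __init__(self, allele: str, message: str | None = None):
        self.allele = allele
        super().__init__(message or f"no passing clones for allele {allele!r}")
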