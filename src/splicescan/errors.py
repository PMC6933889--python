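"""Exception hierarchy shared by all splicescan modules."""


class SpliceScanError(Exception):
    """Base class for all splicescan errors."""


class FormatError(SpliceScanError, ValueError):
    """A text file does not conform to its declared format.

    ``line`` is the 1-based line number at which the problem was detected,
    or ``None`` when no single line can be blamed.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class FastaFormatError(FormatError):
    pass


class GtfFormatError(FormatError):
    pass


class AlphabetError(SpliceScanError, ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class CoordinateError(SpliceScanError, ValueError):
    """A 1-based coordinate or interval falls outside its sequence."""


class CapacityError(SpliceScanError, ValueError):
    """Not enough source material (sites, midpoints, windows) for a request."""


class ConfigError(SpliceScanError, ValueError):
    """An invalid parameter combination in a config or model spec."""


class ShapeError(SpliceScanError, ValueError):
    """Array/window dimensions do not match what an operation expects."""


class ModelStateError(SpliceScanError, RuntimeError):
    """Operation requires an initialized/trained model and got none."""


class ModelLoadError(SpliceScanError, RuntimeError):
    """A saved model directory is missing, incompatible or corrupt."""
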