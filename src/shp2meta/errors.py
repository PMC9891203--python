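"""Exception hierarchy shared across the package."""


class Shp2MetaError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(Shp2MetaError):
    """A PDB record could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class NoAtomsError(Shp2MetaError):
    """A selection or chain filter produced no atoms where some are required."""


class MissingAtomError(Shp2MetaError):
    """A named anchor atom could not be resolved in a structure."""


class DegenerateGeometryError(Shp2MetaError):
    """Coincident or collinear points where a well-defined geometry is needed."""


class ParameterError(Shp2MetaError):
    """Invalid or missing numerical parameters (force field, MetaD, config)."""


class ConfigError(Shp2MetaError):
    """Invalid configuration file content."""
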