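"""Exception hierarchy for porescan."""


class PorescanError(Exception):
    """Base class for all porescan errors."""


class PDBParseError(PorescanError):
    """A PDB coordinate record could not be parsed.

    Carries the 1-based line number of the offending record.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class TopologyError(PorescanError):
    """Topology invariant violated (duplicate ids, bad domain ranges, ...)."""


class TrajectoryError(PorescanError):
    """Trajectory could not be read or is inconsistent with its topology."""


class SelectionError(PorescanError):
    """A selection expression is malformed or resolves to zero atoms."""


class DegenerateGeometryError(PorescanError):
    """Geometry input degenerate (collinear fit set, collinear ring, ...)."""


class WindowError(PorescanError):
    """A time window does not intersect the series in enough frames."""


class ScheduleConflictError(PorescanError):
    """Two scripted events move the same atoms during overlapping transitions."""


class ConfigError(PorescanError):
    """Run configuration is invalid (unknown keys, missing fields, bad values)."""
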