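"""Exception hierarchy for the lesion-atom pipeline."""


class LesionAtomsError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(LesionAtomsError):
    """A configuration value violates its constraints."""


class SchemaError(LesionAtomsError):
    """A table or atlas does not match the expected schema."""


class FormatError(LesionAtomsError):
    """An input file or array has the wrong format (e.g. non-binary mask)."""


class GeometryError(LesionAtomsError):
    """Mask and atlas grids or affines do not match."""


class CapacityError(LesionAtomsError):
    """A requested lesion load exceeds the voxel capacity of a region."""


class AlignmentError(LesionAtomsError):
    """Row-aligned inputs have mismatched lengths or identifiers."""


class DomainError(LesionAtomsError):
    """A numeric input lies outside the mathematical domain of an operation."""


class UndefinedStatisticError(LesionAtomsError):
    """A requested statistic is undefined on the given input (e.g. constant data)."""
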