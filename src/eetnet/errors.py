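"""Exception hierarchy for eetnet."""


class EetError(Exception):
    """Base class for all eetnet errors."""


class StructureParseError(EetError):
    """A structure file could not be parsed."""


class StructureFormatError(EetError):
    """An unknown or unsupported structure format was requested."""


class LigandGeometryError(EetError):
    """A pigment site lacks the atoms required for a geometric operation."""


class GeometryError(EetError):
    """Degenerate geometry (coincident points, zero-length vectors, ...)."""


class SelectionError(EetError):
    """A residue/atom selection resolved to nothing usable."""


class ClassificationError(EetError):
    """Layer classification failed (degenerate spread along the normal)."""


class FixtureValidationError(EetError):
    """A synthetic fixture specification is invalid."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid fixture spec: " + "; ".join(self.violations))


class PipelineConfigError(EetError):
    """A pipeline run configuration is invalid."""
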