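"""Exception hierarchy.

Every error raised by the library derives from :class:`ConfdynError` so
callers (and the pipeline's per-stage error capture) can catch library
failures without swallowing programming errors.
"""


class ConfdynError(Exception):
    """Base class for all library errors."""


class ParseError(ConfdynError):
    """A coordinate file could not be parsed; message carries the line number."""


class StructureInconsistencyError(ConfdynError):
    """Models within one multi-model file disagree in atom count or ordering."""


class FormatOverflowError(ConfdynError):
    """A coordinate does not fit the fixed PDB columns."""


class EmptySelectionError(ConfdynError):
    """An atom selection matched nothing."""


class AmbiguousAtomError(ConfdynError):
    """A selection that must name exactly one atom matched several."""


class CorrespondenceError(ConfdynError):
    """A selection resolves differently on two topologies that must match."""


class DegenerateGeometryError(ConfdynError):
    """Point sets too degenerate for a unique rigid superposition."""


class SamplingError(ConfdynError):
    """Requested more frames than the ensemble holds."""


class MissingAtomError(ConfdynError):
    """A residue lacks a backbone atom needed for a torsion."""


class ChainBreakError(ConfdynError):
    """Residue numbering of the analysis chain is not consecutive."""


class SchemaError(ConfdynError):
    """Dihedral matrices from different conditions disagree in columns."""


class ScalingError(ConfdynError):
    """A feature column has zero variance and cannot be standard-scaled."""


class DegenerateExtentError(ConfdynError):
    """All projected points coincide; no histogram extent exists."""


class ClusteringError(ConfdynError):
    """Fewer distinct points than requested clusters."""


class ValidationError(ConfdynError):
    """An input value violates a documented precondition."""


class SpecError(ConfdynError):
    """A synthetic-ensemble specification is invalid."""


class ProvenanceError(ConfdynError):
    """A realization was paired with a spec that did not produce it."""


class ConfigError(ConfdynError):
    """An analysis configuration file is invalid."""
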