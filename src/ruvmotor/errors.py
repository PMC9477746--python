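"""Exception hierarchy shared across the package."""


class RuvmotorError(Exception):
    """Base class for all package-specific errors."""


class ParseError(RuvmotorError):
    """A coordinate file could not be parsed or violates a container invariant."""


class FormatError(RuvmotorError):
    """An unknown or unsupported coordinate format was requested."""


class ManifestError(RuvmotorError):
    """A state manifest is missing, malformed, or internally inconsistent."""


class GeometryError(RuvmotorError):
    """Degenerate or inconsistent geometric input."""


class DecompositionError(RuvmotorError):
    """A motor state could not be decomposed into subunits/clusters."""


class AmbiguousPocketError(DecompositionError):
    """More than one nucleotide ligand matched a single binding pocket."""


class MetricError(RuvmotorError):
    """A conformational metric could not be evaluated on the given states."""


class CycleError(RuvmotorError):
    """Invalid input to the nucleotide-cycle state machine."""


class ConfigError(RuvmotorError):
    """Invalid run configuration."""
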