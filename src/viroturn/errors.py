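"""Exception hierarchy for the viroturn pipeline."""


class ViroturnError(Exception):
    """Base class for all viroturn errors."""


class SpecificationError(ViroturnError):
    """A simulation specification field is out of its documented range."""


class FormatError(ViroturnError):
    """A file does not conform to its declared format."""


class ConfigError(ViroturnError):
    """Run configuration is invalid or contains unknown keys."""


class DataError(ViroturnError):
    """A record is missing information required by an operation."""


class EvidenceError(ViroturnError):
    """Detector evidence is incomplete for a contig."""


class GraphError(ViroturnError):
    """A graph input violates a structural precondition (e.g. asymmetry)."""


class DegenerateCommunityError(ViroturnError):
    """A sorted fraction was requested but the community places zero mass in it."""


class UndefinedRatioError(ViroturnError):
    """A progeny ratio was requested for a cluster with no countable members."""
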