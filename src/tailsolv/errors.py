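"""Exception hierarchy shared by all pipeline stages."""


class TailsolvError(Exception):
    """Base class for all package-specific errors."""


class EmptyStructureError(TailsolvError):
    """A structure source yielded zero standard residues."""


class SegmentRangeError(TailsolvError):
    """A segment or truncation does not fit the chain it names."""


class UnsupportedResidueError(TailsolvError):
    """A residue outside the 20 standard amino acids where one is required."""


class ParameterizationError(TailsolvError):
    """An atom or residue has no entry in the active parameter/radius table."""


class GeometryError(TailsolvError):
    """Degenerate coordinates: overlapping atoms, missing CA, <3 non-collinear points."""


class CorrespondenceError(TailsolvError):
    """Two structures that must share sequence/atom naming do not."""


class InsufficientEnsembleError(TailsolvError):
    """An ensemble operation needs more models than were provided."""


class UndefinedEntropyError(TailsolvError):
    """Shannon entropy requested for an empty composite sequence."""


class MetadataError(TailsolvError):
    """A mandatory reference-set metadata field is missing."""


class GenerationError(TailsolvError):
    """The synthetic generator could not satisfy its constraints; reseed or relax."""
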