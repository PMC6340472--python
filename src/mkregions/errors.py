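"""Exception hierarchy.

Every rejected input maps to a distinct subclass so callers (and the CLI)
can distinguish a ragged alignment from, say, an unreadable file without
string-matching messages.
"""


class MKRegionsError(Exception):
    """Base class for all package errors."""


class AlignmentFileError(MKRegionsError):
    """A FASTA file is missing or unparseable."""


class RaggedAlignmentError(MKRegionsError):
    """Sequences within the alignment differ in length."""


class FrameError(MKRegionsError):
    """Alignment length is not a multiple of three."""


class SampleSizeError(MKRegionsError):
    """A focal species has fewer than two lines."""


class DuplicateIdError(MKRegionsError):
    """Two FASTA records share the same line id."""


class AlphabetError(MKRegionsError):
    """A sequence contains characters outside {A, C, G, T, N, -}."""


class PartitionError(MKRegionsError):
    """Base for region-partition config problems."""


class RegionOverlapError(PartitionError):
    """Two regions share at least one codon."""


class RegionBoundsError(PartitionError):
    """A region interval is empty, non-positive, or exceeds the CDS."""


class DuplicateRegionError(PartitionError):
    """Two regions share a name."""


class StopCodonError(MKRegionsError):
    """A stop codon was supplied where a sense codon is required."""


class MissingOutgroupError(MKRegionsError):
    """Polarization requested but the alignment has no outgroup."""


class MotifSyntaxError(MKRegionsError):
    """Malformed PROSITE-style pattern; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class SimulationError(MKRegionsError):
    """Invalid simulation configuration or infeasible request."""
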