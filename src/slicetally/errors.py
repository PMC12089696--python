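"""Exception hierarchy shared across the package."""


class SliceTallyError(Exception):
    """Base class for all package errors."""


class RegionParseError(SliceTallyError, ValueError):
    """Region string does not match ``contig:start-end``."""


class RegionBoundsError(SliceTallyError, ValueError):
    """Region start exceeds end, or coordinates are out of range."""


class GeneLookupError(SliceTallyError, KeyError):
    """Requested gene symbols are absent from the annotation."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"gene symbol(s) not found in annotation: {', '.join(self.missing)}")


class ContigError(SliceTallyError, ValueError):
    """A contig named in a region is absent from a BAM header or reference."""


class MissingIndexError(SliceTallyError, OSError):
    """BAM index (.bai) is required but absent."""


class ManifestError(SliceTallyError, ValueError):
    """Manifest invariant violated (e.g. duplicate file ids)."""


class AuthConfigurationError(SliceTallyError, OSError):
    """Token file missing or empty before any request was issued."""


class DownloadIntegrityError(SliceTallyError, OSError):
    """Downloaded BAM fails the magic/EOF integrity check."""


class GffStructureError(SliceTallyError, ValueError):
    """GFF3 hierarchy violated (e.g. exon outside its transcript span)."""


class RefMismatchError(SliceTallyError, ValueError):
    """Variant ref allele disagrees with the reference sequence."""


class ParameterError(SliceTallyError, ValueError):
    """Invalid parameter value (unknown mode, negative threshold, ...)."""


class CsqFormatError(SliceTallyError, ValueError):
    """VCF lacks a parseable CSQ INFO declaration."""
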