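"""Exception hierarchy for absearch."""


class AbsearchError(Exception):
    """Base class for all absearch errors."""


class ParseError(AbsearchError):
    """A text input (numbering table, scheme definition, manifest) is malformed."""


class SchemeError(AbsearchError):
    """A canonical scheme definition is invalid or two schemes do not match."""


class EncodingError(AbsearchError):
    """A residue cannot be encoded under the scheme's alphabet.

    Distinct from an *unusual* sequence: an unusual sequence carries a
    position absent from the scheme and is routed to a sidecar, while an
    encoding error is a hard input defect.
    """


class BackendUnavailableError(AbsearchError):
    """The configured external numbering backend cannot be used."""


class BuildError(AbsearchError):
    """Database construction failed (count mismatch, scheme mismatch, ...)."""


class LoadError(AbsearchError):
    """A persisted database failed an integrity check on load."""


class ResolutionError(AbsearchError):
    """An (file_id, row) index pair does not resolve to a metadata record."""


class RegionError(AbsearchError):
    """A region mask refers to positions outside the scheme, or is empty."""


class SearchError(AbsearchError):
    """A search request is inconsistent with the database it targets."""
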