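"""Exception hierarchy for provenance-replay failures.

Every error raised by this package derives from :class:`ProvReplayError`,
so callers can catch one base class at CLI boundaries.
"""


class ProvReplayError(Exception):
    """Base class for all errors raised by provreplay."""


class ArchiveFormatError(ProvReplayError):
    """The file is not a readable ZIP archive."""


class MalformedArchiveError(ProvReplayError):
    """The ZIP is readable but violates the result-archive layout."""


class MissingMemberError(ProvReplayError):
    """A requested archive member does not exist."""


class NoArchivesFoundError(ProvReplayError):
    """Discovery over the given paths produced no result archives."""


class UnparseableManifestError(ProvReplayError):
    """A checksum manifest line does not match the md5sum dialect."""


class DuplicateEntryError(UnparseableManifestError):
    """A checksum manifest lists the same path twice."""


class UnparseableVersionError(ProvReplayError):
    """The VERSION file does not match the three-line dialect."""


class SchemaError(ProvReplayError):
    """An action record violates the action.yaml schema."""


class InconsistentProvenanceError(ProvReplayError):
    """A provenance subtree's recorded identity contradicts its location."""


class CorruptProvenanceError(ProvReplayError):
    """Provenance records imply a cyclic dependency graph."""


class ConflictError(ProvReplayError):
    """Two records claim the same identity with different content."""


class MissingNodeError(ProvReplayError):
    """A UUID was requested that is not present in the graph."""


class CodegenError(ProvReplayError):
    """A recorded value cannot be rendered in the requested dialect."""


class BibParseError(ProvReplayError):
    """A citations file yielded no parseable BibTeX entries."""


class FixtureSpecError(ProvReplayError):
    """A synthetic-analysis spec is internally impossible."""
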