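"""MD5 checksum-manifest computation and validation.

Each archive (format version >= 2) carries ``<root>/checksums.md5`` in the
md5sum dialect: one ``<32 hex digits><two spaces><path>`` line per member,
paths relative to the root-UUID directory, sorted lexicographically, the
manifest itself excluded. Validation rehashes every member and reports —
never raises on — alterations, so provenance consumers can decide whether
a tampered archive still merits replay.

Validation deliberately trusts as little as possible: it works directly on
the ZIP, without requiring the archive's identity files to parse, because
those files are exactly what tampering may have corrupted. MD5 here is an
integrity alert against accidental modification, not a security boundary.
"""

from __future__ import annotations

import hashlib
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

from .archive_model import ResultArchive
from .errors import DuplicateEntryError, UnparseableManifestError

_LINE_RE = re.compile(r"^(?P<digest>[0-9a-f]{32})  (?P<path>.+)$")

VALID = "valid"
INVALID = "invalid"
PREDATES_CHECKSUMS = "predates-checksums"
UNPARSEABLE = "unparseable"


@dataclass
class ChecksumManifest:
    """Ordered map of archive-relative path -> lowercase hex MD5 digest."""

    entries: dict[str, str] = field(default_factory=dict)


@dataclass
class ValidationReport:
    """Outcome of validating one archive against its manifest.

    ``mismatches`` holds ``(path, expected digest, observed digest or
    "missing")`` triples; ``extras`` lists members present in the archive
    but absent from the manifest.
    """

    status: str
    mismatches: list[tuple[str, str, str]] = field(default_factory=list)
    extras: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.status in (VALID, PREDATES_CHECKSUMS)


def compute_md5(content: bytes) -> str:
    """RFC-1321 MD5 digest of *content*, lowercase hex."""
    return hashlib.md5(content).hexdigest()


def parse_checksum_manifest(text: str) -> ChecksumManifest:
    """Parse md5sum-dialect manifest text, preserving line order."""
    manifest = ChecksumManifest()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        match = _LINE_RE.match(line)
        if match is None:
            raise UnparseableManifestError(
                f"manifest line {lineno} does not match the md5sum dialect: {line!r}"
            )
        path = match["path"]
        if path in manifest.entries:
            raise DuplicateEntryError(f"manifest line {lineno}: duplicate path {path!r}")
        manifest.entries[path] = match["digest"]
    return manifest


def render_checksum_manifest(entries: dict[str, str]) -> str:
    """Serialize digests in the manifest dialect (sorted, LF endings)."""
    return "".join(f"{digest}  {path}\n" for path, digest in sorted(entries.items()))


def _legacy_version(zf: zipfile.ZipFile, root: str) -> bool | None:
    """True if the VERSION file marks a pre-manifest archive; None if unreadable."""
    from .prov_parse import parse_version

    try:
        version = parse_version(zf.read(f"{root}/VERSION").decode("utf-8"))
    except Exception:  # noqa: BLE001 - any corruption means "cannot tell"
        return None
    return version.archive_version < 2


def validate_path(path: str | Path) -> ValidationReport:
    """Rehash every member of the archive at *path* against its manifest.

    Returns a report rather than raising: ``valid`` when everything
    matches; ``invalid`` on any mismatched, missing or unlisted member
    (including a missing manifest in a format-version >= 2 archive);
    ``predates-checksums`` for format-version-1 archives, which never
    carried manifests; ``unparseable`` when the container or the manifest
    itself cannot be read.
    """
    path = Path(path)
    if not zipfile.is_zipfile(path):
        return ValidationReport(status=UNPARSEABLE)
    with zipfile.ZipFile(path) as zf:
        members = [info.filename for info in zf.infolist() if not info.is_dir()]
        roots = {member.split("/", 1)[0] for member in members}
        if len(roots) != 1:
            return ValidationReport(status=UNPARSEABLE)
        (root,) = roots
        manifest_member = f"{root}/checksums.md5"
        if manifest_member not in members:
            legacy = _legacy_version(zf, root)
            if legacy:
                return ValidationReport(status=PREDATES_CHECKSUMS)
            # a version >= 2 (or undecidable) archive promises a manifest;
            # its absence is itself an alteration
            return ValidationReport(
                status=INVALID,
                mismatches=[("checksums.md5", "present", "missing")],
            )
        try:
            manifest = parse_checksum_manifest(zf.read(manifest_member).decode("utf-8"))
        except (UnparseableManifestError, UnicodeDecodeError):
            return ValidationReport(status=UNPARSEABLE)
        observed = {
            member[len(root) + 1 :]: compute_md5(zf.read(member))
            for member in members
            if member != manifest_member
        }
    mismatches: list[tuple[str, str, str]] = []
    for relpath, expected in manifest.entries.items():
        got = observed.get(relpath)
        if got is None:
            mismatches.append((relpath, expected, "missing"))
        elif got != expected:
            mismatches.append((relpath, expected, got))
    extras = sorted(set(observed) - set(manifest.entries))
    status = VALID if not mismatches and not extras else INVALID
    return ValidationReport(status=status, mismatches=mismatches, extras=extras)


def validate_checksums(archive: ResultArchive) -> ValidationReport:
    """Validate an already-opened archive (see :func:`validate_path`)."""
    return validate_path(archive.root_path)
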