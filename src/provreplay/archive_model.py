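"""Result-archive format: on-disk layout and read-only access.

A *result archive* is a ZIP file holding one analysis result plus its own
retrospective provenance. The layout is a single top-level directory named
by the result's version-4 UUID::

    <uuid>/VERSION
    <uuid>/metadata.yaml
    <uuid>/checksums.md5          # archive_version >= 2
    <uuid>/data/...               # opaque payload, never interpreted here
    <uuid>/provenance/VERSION
    <uuid>/provenance/metadata.yaml
    <uuid>/provenance/citations.bib
    <uuid>/provenance/action/action.yaml
    <uuid>/provenance/artifacts/<ancestor-uuid>/{VERSION,metadata.yaml,
                                                 citations.bib,action/action.yaml}

Reading an archive indexes members and parses the small identity files;
payload bytes are never extracted to disk.
"""

from __future__ import annotations

import logging
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

from .errors import (
    ArchiveFormatError,
    MalformedArchiveError,
    MissingMemberError,
    NoArchivesFoundError,
)

logger = logging.getLogger(__name__)

#: Version-4 UUID: 8-4-4-4-12 lowercase hex, version nibble 4, variant 8/9/a/b.
UUID4_RE = re.compile(
    r"^[0-9a-f]{8}-[0-9a-f]{4}-4[0-9a-f]{3}-[89ab][0-9a-f]{3}-[0-9a-f]{12}$"
)

#: File extensions accepted during directory discovery.
ARCHIVE_EXTENSIONS = (".zip", ".qza", ".qzv")


def is_uuid4(value: object) -> bool:
    return isinstance(value, str) and bool(UUID4_RE.match(value))


@dataclass(frozen=True)
class ResultMetadata:
    """Identity record of a single result: who it is and what it holds."""

    uuid: str
    semantic_type: str
    data_format: str

    def __post_init__(self) -> None:
        if not is_uuid4(self.uuid):
            raise MalformedArchiveError(f"not a version-4 UUID: {self.uuid!r}")
        if not self.semantic_type:
            raise MalformedArchiveError("semantic_type must be non-empty")
        if not self.data_format:
            raise MalformedArchiveError("data_format must be non-empty")


@dataclass(frozen=True)
class VersionInfo:
    """Framework and archive-format versions recorded in a VERSION file."""

    framework_version: str
    archive_version: int

    def __post_init__(self) -> None:
        if self.archive_version < 1:
            from .errors import UnparseableVersionError

            raise UnparseableVersionError(
                f"archive version must be >= 1, got {self.archive_version}"
            )


@dataclass(frozen=True)
class ResultArchive:
    """An on-disk zipped result, indexed but not extracted."""

    root_path: Path
    root_uuid: str
    metadata: ResultMetadata
    version: VersionInfo
    member_paths: tuple[str, ...] = field(repr=False)

    @property
    def manifest_path(self) -> str:
        return f"{self.root_uuid}/checksums.md5"

    def has_member(self, relpath: str) -> bool:
        return relpath in self.member_paths


def _load_metadata_yaml(text: bytes | str) -> ResultMetadata:
    if isinstance(text, bytes):
        text = text.decode("utf-8")
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise MalformedArchiveError(f"unparseable metadata.yaml: {exc}") from exc
    if not isinstance(doc, dict):
        raise MalformedArchiveError("metadata.yaml is not a mapping")
    try:
        return ResultMetadata(
            uuid=doc["uuid"], semantic_type=doc["type"], data_format=doc["format"]
        )
    except KeyError as exc:
        raise MalformedArchiveError(f"metadata.yaml missing key {exc}") from exc


def read_archive(path: str | Path) -> ResultArchive:
    """Open a result archive and parse its identity files.

    Payload under ``data/`` is indexed only; the provenance tree is left
    for :func:`provreplay.prov_parse.parse_provenance_tree`.

    Raises
    ------
    ArchiveFormatError
        if *path* is not a ZIP file.
    MalformedArchiveError
        if the internal layout violates the single-root contract or the
        required identity files are missing or inconsistent.
    """
    path = Path(path)
    if not zipfile.is_zipfile(path):
        raise ArchiveFormatError(f"not a ZIP archive: {path}")
    with zipfile.ZipFile(path) as zf:
        members = tuple(
            sorted(info.filename for info in zf.infolist() if not info.is_dir())
        )
        roots = {name.split("/", 1)[0] for name in members}
        if len(roots) != 1:
            raise MalformedArchiveError(
                f"{path}: expected exactly one top-level directory, "
                f"found {sorted(roots)}"
            )
        (root,) = roots
        for required in (f"{root}/metadata.yaml", f"{root}/VERSION"):
            if required not in members:
                raise MalformedArchiveError(f"{path}: missing member {required}")
        metadata = _load_metadata_yaml(zf.read(f"{root}/metadata.yaml"))
        if metadata.uuid != root:
            raise MalformedArchiveError(
                f"{path}: metadata uuid {metadata.uuid} != root directory {root}"
            )
        # deferred import: parse_version lives with the provenance parsers
        from .prov_parse import parse_version

        version = parse_version(zf.read(f"{root}/VERSION").decode("utf-8"))
    return ResultArchive(
        root_path=path,
        root_uuid=root,
        metadata=metadata,
        version=version,
        member_paths=members,
    )


def discover_archives(paths: Iterable[str | Path]) -> list[ResultArchive]:
    """Read archives from files and recursively scanned directories.

    Files named directly are read (errors propagate); directory scans
    accept ``.zip``/``.qza``/``.qzv`` candidates and skip unreadable ones
    with a logged notice. The result is sorted by root UUID. Duplicate
    paths yield duplicate entries — deduplication is the DAG layer's job.
    """
    found: list[ResultArchive] = []
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise ArchiveFormatError(f"no such path: {path}")
        if path.is_dir():
            for candidate in sorted(path.rglob("*")):
                if candidate.suffix.lower() not in ARCHIVE_EXTENSIONS:
                    continue
                try:
                    found.append(read_archive(candidate))
                except Exception as exc:  # noqa: BLE001 - skip, don't abort scan
                    logger.warning("skipping unreadable candidate %s: %s", candidate, exc)
        else:
            found.append(read_archive(path))
    if not found:
        raise NoArchivesFoundError(f"no archives found under {list(map(str, paths))}")
    found.sort(key=lambda a: a.root_uuid)
    return found


def read_member(archive: ResultArchive, relpath: str) -> bytes:
    """Return the exact stored bytes of one archive member."""
    if relpath not in archive.member_paths:
        raise MissingMemberError(f"{archive.root_path}: no member {relpath!r}")
    with zipfile.ZipFile(archive.root_path) as zf:
        return zf.read(relpath)
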