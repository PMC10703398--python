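"""BibTeX collection, deduplication and rendering for replayed analyses.

Every provenance subtree carries a ``citations.bib`` whose keys are
namespaced per attribution target: ``framework|<version>``,
``plugin|<name>|<version>`` and ``action|<plugin>|<action>|<n>``.
Collation walks the DAG in topological order, resolves each node's keys
against its own bib file, then deduplicates: entries sharing a
normalized DOI merge (first wins); DOI-less entries dedup on exact key;
surviving key collisions are disambiguated with ``_a``, ``_b``, ...
suffixes. DOIs are the only identity that survives per-result key
namespacing, hence the DOI-first precedence.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field

from .errors import BibParseError

logger = logging.getLogger(__name__)


@dataclass
class CitationEntry:
    """One BibTeX record: ``@entry_type{key, field = {value}, ...}``."""

    key: str
    entry_type: str
    fields: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entry_type = self.entry_type.lower()

    @property
    def doi(self) -> str | None:
        raw = self.fields.get("doi")
        return normalize_doi(raw) if raw else None


def normalize_doi(raw: str) -> str:
    """Case-fold and strip resolver/URL prefixes from a DOI string."""
    doi = raw.strip().casefold()
    for prefix in (
        "https://doi.org/",
        "http://doi.org/",
        "https://dx.doi.org/",
        "http://dx.doi.org/",
        "doi:",
    ):
        if doi.startswith(prefix):
            doi = doi[len(prefix) :]
    return doi


def _read_value(text: str, pos: int) -> tuple[str, int]:
    """Read one field value starting at *pos*: braced, quoted, or bare."""
    while pos < len(text) and text[pos] in " \t\r\n":
        pos += 1
    if pos >= len(text):
        raise ValueError("unexpected end of entry")
    char = text[pos]
    if char == "{":
        depth, start = 1, pos + 1
        pos += 1
        while pos < len(text) and depth:
            if text[pos] == "{":
                depth += 1
            elif text[pos] == "}":
                depth -= 1
            pos += 1
        if depth:
            raise ValueError("unbalanced braces in value")
        return text[start : pos - 1], pos
    if char == '"':
        start = pos + 1
        pos += 1
        while pos < len(text) and text[pos] != '"':
            pos += 1
        if pos >= len(text):
            raise ValueError("unterminated quoted value")
        return text[start:pos], pos + 1
    start = pos
    while pos < len(text) and text[pos] not in ",}\n":
        pos += 1
    return text[start:pos].strip(), pos


def _parse_entry(text: str, start: int) -> tuple[CitationEntry | None, int]:
    """Parse one ``@type{...}`` starting at the ``@``; returns (entry, next pos)."""
    pos = start + 1
    type_start = pos
    while pos < len(text) and (text[pos].isalnum() or text[pos] in "-_"):
        pos += 1
    entry_type = text[type_start:pos].strip().lower()
    while pos < len(text) and text[pos] in " \t\r\n":
        pos += 1
    if pos >= len(text) or text[pos] != "{" or not entry_type:
        raise ValueError("malformed entry header")
    pos += 1
    key_start = pos
    while pos < len(text) and text[pos] != ",":
        if text[pos] == "}":
            raise ValueError("entry has no fields")
        pos += 1
    key = text[key_start:pos].strip()
    if not key:
        raise ValueError("empty citation key")
    pos += 1
    fields: dict[str, str] = {}
    while True:
        while pos < len(text) and text[pos] in " \t\r\n,":
            pos += 1
        if pos >= len(text):
            raise ValueError("unterminated entry")
        if text[pos] == "}":
            return CitationEntry(key=key, entry_type=entry_type, fields=fields), pos + 1
        name_start = pos
        while pos < len(text) and text[pos] not in "=\n}":
            pos += 1
        if pos >= len(text) or text[pos] != "=":
            raise ValueError("field without '='")
        name = text[name_start:pos].strip().lower()
        value, pos = _read_value(text, pos + 1)
        fields[name] = value


def parse_bibtex(text: str) -> list[CitationEntry]:
    """Parse BibTeX text; unparseable entries are skipped with a warning.

    ``%``-prefixed lines are comments. Raises :class:`BibParseError` only
    when the text contains entry markers but none parse.
    """
    body = "\n".join(
        line for line in text.splitlines() if not line.lstrip().startswith("%")
    )
    entries: list[CitationEntry] = []
    saw_marker = False
    pos = 0
    while True:
        pos = body.find("@", pos)
        if pos == -1:
            break
        saw_marker = True
        try:
            entry, pos = _parse_entry(body, pos)
            if entry is not None:
                entries.append(entry)
        except ValueError as exc:
            logger.warning("skipping unparseable BibTeX entry at offset %d: %s", pos, exc)
            pos += 1
    if saw_marker and not entries:
        raise BibParseError("no parseable BibTeX entries in non-empty input")
    return entries


def collect_citations(dag, archives) -> list[CitationEntry]:
    """Resolve every full-provenance node's citation keys across archives.

    Entries come back in topological-order-of-first-appearance and may
    contain duplicates; pass through :func:`dedup_citations` to collate.
    """
    from .prov_dag import topological_order
    from .prov_parse import parse_provenance_tree, resolve_citation_keys

    per_uuid: dict[str, tuple] = {}
    for archive in archives:
        for node in parse_provenance_tree(archive):
            if node.has_provenance and node.result_uuid not in per_uuid:
                per_uuid[node.result_uuid] = (archive, node)
    entries: list[CitationEntry] = []
    for uuid in topological_order(dag):
        located = per_uuid.get(uuid)
        if located is None:
            continue
        archive, node = located
        entries.extend(resolve_citation_keys(archive, node))
    return entries


def dedup_citations(entries: list[CitationEntry]) -> list[CitationEntry]:
    """Merge duplicates (DOI first, then exact key); disambiguate keys."""
    kept: list[CitationEntry] = []
    by_doi: dict[str, int] = {}
    by_key: dict[str, int] = {}
    for entry in entries:
        doi = entry.doi
        if doi is not None:
            if doi in by_doi:
                continue
            by_doi[doi] = len(kept)
        else:
            if entry.key in by_key:
                continue
            by_key[entry.key] = len(kept)
        kept.append(entry)

    used: set[str] = set()
    out: list[CitationEntry] = []
    suffixes = [
        "".join(combo)
        for size in (1, 2)
        for combo in itertools.product(string.ascii_lowercase, repeat=size)
    ]
    for entry in kept:
        key = entry.key
        if key in used:
            # collision among survivors: suffix _a, _b, ... in arrival order
            key = next(
                f"{entry.key}_{suffix}"
                for suffix in suffixes
                if f"{entry.key}_{suffix}" not in used
            )
        used.add(key)
        out.append(CitationEntry(key=key, entry_type=entry.entry_type,
                                 fields=dict(entry.fields)))
    return out


def render_bibtex(entries: list[CitationEntry]) -> str:
    """Deterministic BibTeX text: given order, stored field order, LF."""
    keys = [entry.key for entry in entries]
    if len(set(keys)) != len(keys):
        raise BibParseError("duplicate keys in bibliography render")
    if not entries:
        return "% no citations recorded\n"
    blocks = []
    for entry in entries:
        lines = [f"@{entry.entry_type}{{{entry.key},"]
        lines.extend(f"  {name} = {{{value}}}," for name, value in entry.fields.items())
        lines.append("}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"
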