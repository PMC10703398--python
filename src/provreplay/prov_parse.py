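"""Parsers for the per-result provenance tree.

Every result archive carries a decentralized provenance record: the
terminal result's own action record plus one subtree per ancestor result,
each holding ``VERSION``, ``metadata.yaml``, ``citations.bib`` and
``action/action.yaml``. The action record captures everything needed to
re-enact one execution — what ran, with which inputs and parameters
(defaults and nulls included), in which software environment, and when.

action.yaml schema (top-level keys)::

    execution: {uuid: <v4 uuid>, runtime: {start: <iso8601>, end: <iso8601>}}
    action:
      type: import | method | visualizer | pipeline
      plugin: <name>            # absent for imports
      action: <name>            # absent for imports
      inputs: [{<name>: <uuid or null>}, ...]       # order-preserving
      parameters: [{<name>: <scalar>}, ...]         # order-preserving
      output-name: <name>
      manifest: [{name: <filename>, md5sum: <hex>}, ...]   # imports only
    environment:
      platform: <os name+version>
      language: <language name+version>
      framework: <version>
      plugins: {<plugin>: <version>, ...}
    citations: [<key>, ...]

Inputs and parameters are lists of single-key maps so their order survives
YAML round-trips. Parameters are flat scalars (or flat lists of scalars);
a metadata-typed parameter is tagged ``!metadata <recorded filename>`` and
loads as :class:`MetadataRef`. Unknown top-level keys are preserved in a
pass-through bag for forward compatibility.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime

import yaml

from .archive_model import (
    ResultArchive,
    ResultMetadata,
    VersionInfo,
    _load_metadata_yaml,
    is_uuid4,
    read_member,
)
from .errors import (
    BibParseError,
    InconsistentProvenanceError,
    SchemaError,
    UnparseableVersionError,
)

logger = logging.getLogger(__name__)

ACTION_TYPES = ("import", "method", "visualizer", "pipeline")

_MD5_RE = re.compile(r"^[0-9a-f]{32}$")

_VERSION_RE = re.compile(
    r"^FORMAT: result-archive\narchive: (?P<archive>\d+)\nframework: (?P<framework>\S+)\n?$"
)


class MetadataRef:
    """A parameter value tagged as sample/feature metadata.

    Carries only the filename recorded at execution time; replay never
    reuses the recorded table silently — codegen turns these into
    placeholder files the user must supply.
    """

    __slots__ = ("filename",)

    def __init__(self, filename: str) -> None:
        self.filename = filename

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MetadataRef) and other.filename == self.filename

    def __hash__(self) -> int:
        return hash(("MetadataRef", self.filename))

    def __repr__(self) -> str:
        return f"MetadataRef({self.filename!r})"


_BaseLoader = getattr(yaml, "CSafeLoader", yaml.SafeLoader)
_BaseDumper = getattr(yaml, "CSafeDumper", yaml.SafeDumper)


class ProvLoader(_BaseLoader):
    """SafeLoader plus the ``!metadata`` local tag."""


class ProvDumper(_BaseDumper):
    """SafeDumper plus the ``!metadata`` local tag."""


ProvLoader.add_constructor(
    "!metadata", lambda loader, node: MetadataRef(loader.construct_scalar(node))
)
ProvDumper.add_representer(
    MetadataRef,
    lambda dumper, ref: dumper.represent_scalar("!metadata", ref.filename),
)


def load_prov_yaml(text: str | bytes):
    if isinstance(text, bytes):
        text = text.decode("utf-8")
    return yaml.load(text, Loader=ProvLoader)


def dump_prov_yaml(doc) -> str:
    return yaml.dump(doc, Dumper=ProvDumper, sort_keys=False, allow_unicode=True)


@dataclass(frozen=True)
class EnvironmentRecord:
    """Software environment an action ran in."""

    platform: str
    language: str
    framework_version: str
    plugin_versions: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ImportManifestEntry:
    """Fingerprint of one file brought in by an import action."""

    filename: str
    md5sum: str

    def __post_init__(self) -> None:
        if not _MD5_RE.match(self.md5sum):
            raise SchemaError(f"import manifest digest not 32-hex: {self.md5sum!r}")


@dataclass(frozen=True)
class ActionRecord:
    """One recorded execution: the unit a replay statement re-enacts.

    ``parameters`` holds every parameter of the action verbatim as
    recorded — defaults and nulls included — keyed in written order.
    ``execution_uuid`` is shared by all outputs of one execution.
    """

    execution_uuid: str
    action_type: str
    plugin: str | None
    action_name: str | None
    inputs: dict[str, str | None]
    parameters: dict[str, object]
    output_name: str
    start_time: str
    end_time: str
    citation_keys: tuple[str, ...] = ()
    import_manifest: tuple[ImportManifestEntry, ...] = ()
    extras: dict = field(default_factory=dict, compare=False)

    @property
    def start_instant(self) -> datetime:
        return datetime.fromisoformat(self.start_time)

    @property
    def end_instant(self) -> datetime:
        return datetime.fromisoformat(self.end_time)

    def same_execution_as(self, other: "ActionRecord") -> bool:
        """True when two records describe the same execution (they may
        differ only in which output they were stored with)."""
        return (
            self.execution_uuid == other.execution_uuid
            and self.action_type == other.action_type
            and self.plugin == other.plugin
            and self.action_name == other.action_name
            and self.inputs == other.inputs
            and self.parameters == other.parameters
            and self.start_time == other.start_time
            and self.end_time == other.end_time
        )


@dataclass(frozen=True)
class ProvNode:
    """One result in the provenance graph.

    ``has_provenance`` is False for results that are referenced but carry
    no action record (data predating provenance capture, or partial
    archives); such nodes surface in replay as user-action-needed
    comments rather than being dropped.
    """

    result_uuid: str
    metadata: ResultMetadata | None = None
    action: ActionRecord | None = None
    environment: EnvironmentRecord | None = None
    has_provenance: bool = False
    bib_relpath: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.has_provenance != (self.action is not None):
            raise SchemaError("has_provenance must track presence of the action record")
        if (self.action is None) != (self.environment is None):
            raise SchemaError("action and environment must be present together")


def parse_version(text: str) -> VersionInfo:
    """Parse the three-line VERSION dialect."""
    match = _VERSION_RE.match(text)
    if match is None:
        raise UnparseableVersionError(f"unparseable VERSION content: {text!r}")
    return VersionInfo(
        framework_version=match["framework"], archive_version=int(match["archive"])
    )


def _ordered_pairs(raw, what: str) -> dict:
    """Flatten a list of single-key maps into an order-preserving dict."""
    if raw is None:
        return {}
    if not isinstance(raw, list):
        raise SchemaError(f"{what} must be a list of single-key maps, got {type(raw)}")
    out: dict = {}
    for item in raw:
        if not isinstance(item, dict) or len(item) != 1:
            raise SchemaError(f"{what} entries must be single-key maps, got {item!r}")
        ((key, value),) = item.items()
        if key in out:
            raise SchemaError(f"duplicate {what} key {key!r}")
        out[key] = value
    return out


def _check_scalar(name: str, value: object) -> None:
    if isinstance(value, (str, int, float, bool, MetadataRef)) or value is None:
        return
    if isinstance(value, list):
        for item in value:
            if not (isinstance(item, (str, int, float, bool)) or item is None):
                raise SchemaError(
                    f"parameter {name!r}: list elements must be scalars, got {item!r}"
                )
        return
    raise SchemaError(f"parameter {name!r}: nested structures are not supported")


def parse_action_yaml(text: str | bytes) -> tuple[ActionRecord, EnvironmentRecord]:
    """Parse one action.yaml into its action and environment records."""
    doc = load_prov_yaml(text)
    if not isinstance(doc, dict):
        raise SchemaError("action.yaml is not a mapping")

    execution = doc.get("execution")
    if not isinstance(execution, dict) or not is_uuid4(execution.get("uuid")):
        raise SchemaError("missing or invalid execution uuid")
    runtime = execution.get("runtime")
    if not isinstance(runtime, dict) or "start" not in runtime or "end" not in runtime:
        raise SchemaError("execution.runtime must carry start and end timestamps")

    action = doc.get("action")
    if not isinstance(action, dict):
        raise SchemaError("missing action section")
    action_type = action.get("type")
    if action_type not in ACTION_TYPES:
        raise SchemaError(f"unknown action type {action_type!r}")

    inputs = _ordered_pairs(action.get("inputs"), "inputs")
    for name, value in inputs.items():
        if value is not None and not is_uuid4(value):
            raise SchemaError(f"input {name!r} is neither null nor a v4 UUID: {value!r}")
    parameters = _ordered_pairs(action.get("parameters"), "parameters")
    for name, value in parameters.items():
        _check_scalar(name, value)

    manifest = tuple(
        ImportManifestEntry(filename=item["name"], md5sum=item["md5sum"])
        for item in action.get("manifest") or ()
    )

    if action_type == "import":
        if inputs:
            raise SchemaError("import records must not declare inputs")
        if action.get("plugin") or action.get("action"):
            raise SchemaError("import records must not name a plugin/action")
        if not manifest:
            raise SchemaError("import records require a non-empty file manifest")
    else:
        if not action.get("plugin") or not action.get("action"):
            raise SchemaError(f"{action_type} records require plugin and action names")

    output_name = action.get("output-name")
    if not output_name:
        raise SchemaError("missing output-name")

    env_doc = doc.get("environment")
    if not isinstance(env_doc, dict) or not env_doc.get("framework"):
        raise SchemaError("missing environment.framework")
    environment = EnvironmentRecord(
        platform=env_doc.get("platform", ""),
        language=env_doc.get("language", ""),
        framework_version=env_doc["framework"],
        plugin_versions=dict(env_doc.get("plugins") or {}),
    )
    if action_type != "import" and not environment.plugin_versions:
        raise SchemaError("non-import records must record plugin versions")

    citations = doc.get("citations") or []
    if not isinstance(citations, list):
        raise SchemaError("citations must be a list of keys")

    known = {"execution", "action", "environment", "citations"}
    extras = {key: value for key, value in doc.items() if key not in known}

    def _iso(value: object) -> str:
        # YAML may resolve unquoted ISO-8601 stamps to datetime objects
        if isinstance(value, datetime):
            return value.isoformat()
        return str(value)

    start, end = _iso(runtime["start"]), _iso(runtime["end"])
    record = ActionRecord(
        execution_uuid=execution["uuid"],
        action_type=action_type,
        plugin=action.get("plugin"),
        action_name=action.get("action"),
        inputs=inputs,
        parameters=parameters,
        output_name=output_name,
        start_time=start,
        end_time=end,
        citation_keys=tuple(citations),
        import_manifest=manifest,
        extras=extras,
    )
    if record.start_instant > record.end_instant:
        raise SchemaError(f"execution ends before it starts: {start} > {end}")
    return record, environment


def _parse_subtree(
    archive: ResultArchive, uuid: str, prefix: str, metadata: ResultMetadata
) -> ProvNode:
    action_path = f"{prefix}/action/action.yaml"
    bib_path = f"{prefix}/citations.bib"
    bib = bib_path if archive.has_member(bib_path) else None
    if not archive.has_member(action_path):
        logger.warning(
            "%s: no action record for %s; retained without provenance",
            archive.root_path,
            uuid,
        )
        return ProvNode(result_uuid=uuid, metadata=metadata, bib_relpath=bib)
    record, environment = parse_action_yaml(read_member(archive, action_path))
    return ProvNode(
        result_uuid=uuid,
        metadata=metadata,
        action=record,
        environment=environment,
        has_provenance=True,
        bib_relpath=bib,
    )


def parse_provenance_tree(archive: ResultArchive) -> list[ProvNode]:
    """Parse the root result's record plus every ancestor subtree.

    Returns one node per result; a subtree lacking ``action/action.yaml``
    yields a ``has_provenance=False`` node with a logged warning. A
    subtree whose recorded uuid contradicts its directory name raises
    :class:`InconsistentProvenanceError`.
    """
    root = archive.root_uuid
    nodes = [
        _parse_subtree(archive, root, f"{root}/provenance", archive.metadata)
    ]
    artifact_prefix = f"{root}/provenance/artifacts/"
    ancestor_uuids = sorted(
        {
            member[len(artifact_prefix) :].split("/", 1)[0]
            for member in archive.member_paths
            if member.startswith(artifact_prefix)
        }
    )
    for uuid in ancestor_uuids:
        prefix = f"{artifact_prefix}{uuid}".rstrip("/")
        metadata = _load_metadata_yaml(read_member(archive, f"{prefix}/metadata.yaml"))
        if metadata.uuid != uuid:
            raise InconsistentProvenanceError(
                f"{archive.root_path}: subtree {uuid} records uuid {metadata.uuid}"
            )
        nodes.append(_parse_subtree(archive, uuid, prefix, metadata))
    return nodes


def resolve_citation_keys(archive: ResultArchive, node: ProvNode):
    """Look up the node's citation keys in its own citations.bib.

    Unmatched keys are warned about, never fatal. Returns entries in the
    order the keys were recorded.
    """
    from .citations import parse_bibtex

    if node.action is None or not node.action.citation_keys:
        return []
    if node.bib_relpath is None:
        logger.warning(
            "%s: node %s has citation keys but no citations.bib",
            archive.root_path,
            node.result_uuid,
        )
        return []
    try:
        text = read_member(archive, node.bib_relpath).decode("utf-8")
    except UnicodeDecodeError as exc:
        raise BibParseError(f"{archive.root_path}:{node.bib_relpath}: {exc}") from exc
    entries = {entry.key: entry for entry in parse_bibtex(text)}
    resolved = []
    for key in node.action.citation_keys:
        entry = entries.get(key)
        if entry is None:
            logger.warning(
                "%s: citation key %r not found in %s",
                archive.root_path,
                key,
                node.bib_relpath,
            )
        else:
            resolved.append(entry)
    return resolved
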