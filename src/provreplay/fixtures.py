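"""Synthetic-analysis generator: valid result archives with known ground truth.

This is the package's test bed, standing in for real analysis outputs.
Each simulated analysis is a random DAG of import and action executions
drawn from a small vocabulary of realistic amplicon-workflow plugin and
action names (demux/emp-single, dada2/denoise-single, taxa/barplot,
diversity/core-metrics, ...), with version-4 UUIDs, monotone timestamps,
environment records, and namespaced citation keys carrying synthetic DOIs
under the reserved test prefix ``10.5555/``. One archive is written per
terminal result, with the full nested provenance of its ancestry and a
correct checksum manifest, so parse -> union over all archives must
reproduce the returned ground-truth DAG exactly.

Generation is fully deterministic per spec (seeded RNG, fixed timestamp
base, fixed ZIP member dates): the same spec writes byte-identical
archives on every run.
"""

from __future__ import annotations

import hashlib
import random
import shutil
import uuid as uuid_module
import zipfile
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

from .archive_model import ResultMetadata
from .errors import FixtureSpecError, MissingMemberError
from .integrity import compute_md5, render_checksum_manifest
from .prov_dag import ProvDAG, build_dag
from .prov_parse import (
    ActionRecord,
    EnvironmentRecord,
    ImportManifestEntry,
    MetadataRef,
    ProvNode,
    dump_prov_yaml,
)

FRAMEWORK_VERSION = "2023.9.0"
_PLATFORM = "Linux-5.15.0-synthetic-x86_64"
_LANGUAGE = "Python 3.11"
_BASE_TIME = datetime(2023, 5, 1, 12, 0, 0, tzinfo=timezone.utc)
_ZIP_DATE = (2023, 5, 1, 0, 0, 0)


@dataclass(frozen=True)
class AnalysisSpec:
    """Shape parameters of one simulated analysis.

    ``shared_ancestry`` points at another spec whose full analysis is
    regenerated (identically, from its own seed) and used as the ancestor
    pool; archives are then written only for the extension's terminals,
    giving two analyses with a shared ancestry chain for union tests.
    """

    seed: int
    n_imports: int = 2
    n_actions: int = 6
    max_inputs_per_action: int = 2
    multi_output_fraction: float = 0.3
    shared_ancestry: "AnalysisSpec | None" = None
    archive_version: int = 2
    metadata_param_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_imports < 0 or self.n_actions < 0:
            raise FixtureSpecError("counts must be non-negative")
        if self.n_actions > 0 and self.n_imports == 0 and self.shared_ancestry is None:
            raise FixtureSpecError("actions need at least one import to draw inputs from")
        if self.max_inputs_per_action < 1:
            raise FixtureSpecError("max_inputs_per_action must be >= 1")
        if self.archive_version < 1:
            raise FixtureSpecError("archive_version must be >= 1")


# --- vocabulary ------------------------------------------------------------

_IMPORT_TYPES = [
    ("EMPSingleEndSequences", "EMPSingleEndDirFmt", "emp_single_end_sequences"),
    (
        "SampleData[SequencesWithQuality]",
        "SingleLanePerSampleSingleEndFastqDirFmt",
        "demux_sequences",
    ),
    ("FeatureData[Sequence]", "DNASequencesDirectoryFormat", "reference_sequences"),
]


@dataclass(frozen=True)
class _Template:
    plugin: str
    action: str
    action_type: str
    input_names: tuple[str, ...]
    outputs: tuple[tuple[str, str, str], ...]  # (output-name, type, format)
    params: tuple[tuple[str, str], ...]  # (name, sampler id)
    metadata_param: str | None = None


_SINGLE = [
    _Template(
        "demux", "emp-single", "method", ("seqs",),
        (("per_sample_sequences", "SampleData[SequencesWithQuality]",
          "SingleLanePerSampleSingleEndFastqDirFmt"),),
        (("rev_comp_barcodes", "bool"), ("rev_comp_mapping_barcodes", "bool"),
         ("golay_error_correction", "bool")),
    ),
    _Template(
        "feature-classifier", "classify-sklearn", "method", ("reads",),
        (("classification", "FeatureData[Taxonomy]", "TSVTaxonomyDirectoryFormat"),),
        (("reads_per_batch", "opt_int"), ("n_jobs", "int"), ("confidence", "float")),
    ),
    _Template(
        "taxa", "barplot", "visualizer", ("table", "taxonomy"),
        (("visualization", "Visualization", "HTML"),),
        (("level_delimiter", "opt_str"),),
        metadata_param="metadata",
    ),
    _Template(
        "feature-table", "summarize", "visualizer", ("table",),
        (("visualization", "Visualization", "HTML"),),
        (),
        metadata_param="sample_metadata",
    ),
]

_MULTI = [
    _Template(
        "dada2", "denoise-single", "method", ("demultiplexed_seqs",),
        (("table", "FeatureTable[Frequency]", "BIOMV210DirFmt"),
         ("representative_sequences", "FeatureData[Sequence]",
          "DNASequencesDirectoryFormat"),
         ("denoising_stats", "SampleData[DADA2Stats]", "DADA2StatsDirFmt")),
        (("trunc_len", "int"), ("trim_left", "int"), ("max_ee", "float"),
         ("pooling_method", "pool"), ("chimera_method", "chimera")),
    ),
    _Template(
        "phylogeny", "align-to-tree-mafft-fasttree", "pipeline", ("sequences",),
        (("alignment", "FeatureData[AlignedSequence]", "AlignedDNAFASTAFormat"),
         ("masked_alignment", "FeatureData[AlignedSequence]", "AlignedDNAFASTAFormat"),
         ("tree", "Phylogeny[Unrooted]", "NewickDirectoryFormat"),
         ("rooted_tree", "Phylogeny[Rooted]", "NewickDirectoryFormat")),
        (("n_threads", "int"), ("mask_max_gap_frequency", "float"),
         ("mask_min_conservation", "float")),
    ),
    _Template(
        "diversity", "core-metrics", "pipeline", ("table",),
        (("rarefied_table", "FeatureTable[Frequency]", "BIOMV210DirFmt"),
         ("observed_features_vector", "SampleData[AlphaDiversity]",
          "AlphaDiversityDirectoryFormat"),
         ("shannon_vector", "SampleData[AlphaDiversity]",
          "AlphaDiversityDirectoryFormat"),
         ("evenness_vector", "SampleData[AlphaDiversity]",
          "AlphaDiversityDirectoryFormat")),
        (("sampling_depth", "int"), ("with_replacement", "bool")),
        metadata_param="metadata",
    ),
]


def _sample_param(kind: str, rng: random.Random):
    if kind == "bool":
        return rng.random() < 0.5
    if kind == "int":
        return rng.randint(0, 5000)
    if kind == "opt_int":
        return None if rng.random() < 0.4 else rng.randint(1, 64)
    if kind == "float":
        return round(rng.uniform(0.0, 10.0), 2)
    if kind == "opt_str":
        return None if rng.random() < 0.5 else ";"
    if kind == "pool":
        return rng.choice(["independent", "pseudo"])
    if kind == "chimera":
        return rng.choice(["consensus", "none", "pooled"])
    raise ValueError(kind)


def synthetic_doi(citation_key: str) -> str:
    """Deterministic test-prefix DOI for a namespaced citation key."""
    return "10.5555/synth." + hashlib.md5(citation_key.encode()).hexdigest()[:10]


def _citation_keys(record_type: str, plugin: str | None, action: str | None):
    keys = [f"framework|{FRAMEWORK_VERSION}"]
    if record_type != "import":
        keys.append(f"plugin|{plugin}|{FRAMEWORK_VERSION}")
        keys.append(f"action|{plugin}|{action}|0")
    return tuple(keys)


def _uuid4(rng: random.Random) -> str:
    return str(uuid_module.UUID(int=rng.getrandbits(128), version=4))


# --- phase 1: in-memory analysis -------------------------------------------


@dataclass
class _Analysis:
    """Ground truth of one simulated analysis, before any archive I/O."""

    nodes: dict[str, ProvNode] = field(default_factory=dict)  # creation order
    consumed: set[str] = field(default_factory=set)
    base_uuids: set[str] = field(default_factory=set)
    n_executions: int = 0

    def pool(self) -> list[str]:
        """Results eligible as inputs (visualizations are terminal-only)."""
        return [
            uid for uid, node in self.nodes.items()
            if node.metadata is not None
            and node.metadata.semantic_type != "Visualization"
        ]

    def terminals(self) -> list[str]:
        """Extension results no other result consumes (creation order)."""
        return [
            uid for uid in self.nodes
            if uid not in self.consumed and uid not in self.base_uuids
        ]


def _times(index: int) -> tuple[str, str]:
    start = _BASE_TIME + timedelta(minutes=2 * index)
    return start.isoformat(), (start + timedelta(minutes=1)).isoformat()


def _add_import(analysis: _Analysis, rng: random.Random) -> None:
    semantic_type, data_format, output_name = rng.choice(_IMPORT_TYPES)
    exec_uuid = _uuid4(rng)
    result_uuid = _uuid4(rng)
    start, end = _times(analysis.n_executions)
    manifest = tuple(
        ImportManifestEntry(
            filename=f"{output_name}_{i}.fastq.gz",
            md5sum=compute_md5(f"{exec_uuid}:{i}".encode()),
        )
        for i in range(rng.randint(1, 3))
    )
    record = ActionRecord(
        execution_uuid=exec_uuid,
        action_type="import",
        plugin=None,
        action_name=None,
        inputs={},
        parameters={},
        output_name=output_name,
        start_time=start,
        end_time=end,
        citation_keys=_citation_keys("import", None, None),
        import_manifest=manifest,
    )
    environment = EnvironmentRecord(
        platform=_PLATFORM, language=_LANGUAGE,
        framework_version=FRAMEWORK_VERSION, plugin_versions={},
    )
    analysis.nodes[result_uuid] = ProvNode(
        result_uuid=result_uuid,
        metadata=ResultMetadata(result_uuid, semantic_type, data_format),
        action=record,
        environment=environment,
        has_provenance=True,
    )
    analysis.n_executions += 1


def _add_action(
    analysis: _Analysis,
    rng: random.Random,
    spec: AnalysisSpec,
    forced_input: str | None = None,
) -> None:
    multi = rng.random() < spec.multi_output_fraction
    template = rng.choice(_MULTI if multi else _SINGLE)
    pool = analysis.pool()
    n_inputs = rng.randint(
        1, max(1, min(spec.max_inputs_per_action, len(pool), len(template.input_names)))
    )
    chosen = rng.sample(pool, n_inputs)
    if forced_input is not None and forced_input not in chosen:
        chosen[0] = forced_input
    inputs: dict[str, str | None] = dict(zip(template.input_names, chosen))
    if rng.random() < 0.2:
        inputs["optional_reference"] = None

    parameters: dict[str, object] = {}
    for name, kind in template.params:
        parameters[name] = _sample_param(kind, rng)
    if template.metadata_param is not None:
        parameters[template.metadata_param] = (
            MetadataRef("sample-metadata.tsv")
            if rng.random() < spec.metadata_param_fraction
            else None
        )

    exec_uuid = _uuid4(rng)
    start, end = _times(analysis.n_executions)
    environment = EnvironmentRecord(
        platform=_PLATFORM, language=_LANGUAGE,
        framework_version=FRAMEWORK_VERSION,
        plugin_versions={template.plugin: FRAMEWORK_VERSION},
    )
    for output_name, semantic_type, data_format in template.outputs:
        result_uuid = _uuid4(rng)
        record = ActionRecord(
            execution_uuid=exec_uuid,
            action_type=template.action_type,
            plugin=template.plugin,
            action_name=template.action,
            inputs=inputs,
            parameters=parameters,
            output_name=output_name,
            start_time=start,
            end_time=end,
            citation_keys=_citation_keys(
                template.action_type, template.plugin, template.action
            ),
        )
        analysis.nodes[result_uuid] = ProvNode(
            result_uuid=result_uuid,
            metadata=ResultMetadata(result_uuid, semantic_type, data_format),
            action=record,
            environment=environment,
            has_provenance=True,
        )
    analysis.consumed.update(uid for uid in chosen)
    analysis.n_executions += 1


def _build(spec: AnalysisSpec) -> _Analysis:
    """Phase 1: build the full analysis graph in memory (no I/O)."""
    if spec.shared_ancestry is not None:
        analysis = _build(spec.shared_ancestry)
        analysis.base_uuids = set(analysis.nodes)
        rng = random.Random(f"{spec.seed}|extension")
        base_pool = [
            uid for uid in analysis.pool()
            if uid in analysis.base_uuids and uid not in analysis.consumed
        ] or [uid for uid in analysis.pool() if uid in analysis.base_uuids]
        forced = rng.choice(base_pool) if base_pool else None
    else:
        analysis = _Analysis()
        rng = random.Random(spec.seed)
        forced = None
    for _ in range(spec.n_imports):
        _add_import(analysis, rng)
    for index in range(spec.n_actions):
        _add_action(analysis, rng, spec, forced_input=forced if index == 0 else None)
        forced = None if index == 0 else forced
    return analysis


def _ancestry_closure(analysis: _Analysis, roots: list[str]) -> list[str]:
    """Roots plus all transitive input ancestors, in creation order."""
    keep: set[str] = set()
    stack = list(roots)
    while stack:
        uid = stack.pop()
        if uid in keep:
            continue
        keep.add(uid)
        record = analysis.nodes[uid].action
        if record is not None:
            stack.extend(u for u in record.inputs.values() if u is not None)
    return [uid for uid in analysis.nodes if uid in keep]


# --- phase 2: archive writing ----------------------------------------------


def _version_text(archive_version: int) -> str:
    return (
        f"FORMAT: result-archive\narchive: {archive_version}\n"
        f"framework: {FRAMEWORK_VERSION}\n"
    )


def _metadata_text(metadata: ResultMetadata) -> str:
    return dump_prov_yaml(
        {"uuid": metadata.uuid, "type": metadata.semantic_type,
         "format": metadata.data_format}
    )


def _action_yaml_text(node: ProvNode) -> str:
    record, environment = node.action, node.environment
    assert record is not None and environment is not None
    action: dict = {"type": record.action_type}
    if record.action_type != "import":
        action["plugin"] = record.plugin
        action["action"] = record.action_name
    action["inputs"] = [{name: value} for name, value in record.inputs.items()]
    action["parameters"] = [{name: value} for name, value in record.parameters.items()]
    action["output-name"] = record.output_name
    if record.import_manifest:
        action["manifest"] = [
            {"name": entry.filename, "md5sum": entry.md5sum}
            for entry in record.import_manifest
        ]
    doc = {
        "execution": {
            "uuid": record.execution_uuid,
            "runtime": {"start": record.start_time, "end": record.end_time},
        },
        "action": action,
        "environment": {
            "platform": environment.platform,
            "language": environment.language,
            "framework": environment.framework_version,
            "plugins": dict(environment.plugin_versions),
        },
        "citations": list(record.citation_keys),
    }
    return dump_prov_yaml(doc)


def _bib_text(node: ProvNode) -> str:
    assert node.action is not None
    blocks = []
    for key in node.action.citation_keys:
        kind = key.split("|", 1)[0]
        blocks.append(
            f"@article{{{key},\n"
            f"  title = {{Synthetic {kind} citation for {key.split('|', 1)[1]}}},\n"
            f"  author = {{Synthetic, A. and Generator, B.}},\n"
            f"  journal = {{Journal of Synthetic Provenance}},\n"
            f"  year = {{2023}},\n"
            f"  doi = {{{synthetic_doi(key)}}},\n"
            f"}}"
        )
    return "\n\n".join(blocks) + "\n"


def _subtree_members(prefix: str, node: ProvNode, archive_version: int):
    yield f"{prefix}/VERSION", _version_text(archive_version).encode()
    assert node.metadata is not None
    yield f"{prefix}/metadata.yaml", _metadata_text(node.metadata).encode()
    yield f"{prefix}/citations.bib", _bib_text(node).encode()
    yield f"{prefix}/action/action.yaml", _action_yaml_text(node).encode()


def write_archive(
    analysis_nodes: dict[str, ProvNode],
    terminal_uuid: str,
    out_dir: Path,
    archive_version: int = 2,
) -> Path:
    """Write one result archive for *terminal_uuid* with full ancestry."""
    node = analysis_nodes[terminal_uuid]
    assert node.metadata is not None
    root = terminal_uuid
    members: dict[str, bytes] = {}
    members[f"{root}/VERSION"] = _version_text(archive_version).encode()
    members[f"{root}/metadata.yaml"] = _metadata_text(node.metadata).encode()
    members[f"{root}/data/{node.action.output_name if node.action else 'payload'}.txt"] = (
        f"synthetic payload for {root}\n".encode()
    )
    for relpath, content in _subtree_members(
        f"{root}/provenance", node, archive_version
    ):
        members[relpath] = content

    ancestors: set[str] = set()
    stack = [terminal_uuid]
    while stack:
        uid = stack.pop()
        record = analysis_nodes[uid].action
        if record is None:
            continue
        for input_uuid in record.inputs.values():
            if input_uuid is not None and input_uuid not in ancestors:
                ancestors.add(input_uuid)
                stack.append(input_uuid)
    for ancestor in sorted(ancestors - {terminal_uuid}):
        prefix = f"{root}/provenance/artifacts/{ancestor}"
        for relpath, content in _subtree_members(
            prefix, analysis_nodes[ancestor], archive_version
        ):
            members[relpath] = content

    if archive_version >= 2:
        digests = {
            relpath[len(root) + 1 :]: compute_md5(content)
            for relpath, content in members.items()
        }
        members[f"{root}/checksums.md5"] = render_checksum_manifest(digests).encode()

    extension = ".qzv" if node.metadata.semantic_type == "Visualization" else ".qza"
    out_path = Path(out_dir) / f"{root}{extension}"
    with zipfile.ZipFile(out_path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for relpath in sorted(members):
            info = zipfile.ZipInfo(relpath, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            zf.writestr(info, members[relpath])
    return out_path


def simulate_analysis(
    spec: AnalysisSpec, out_dir: str | Path
) -> tuple[list[Path], ProvDAG]:
    """Generate a synthetic analysis and write one archive per terminal.

    Returns the archive paths (sorted) and the ground-truth provenance
    DAG those archives jointly encode.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    analysis = _build(spec)
    terminals = analysis.terminals()
    if not terminals:
        raise FixtureSpecError("analysis produced no terminal results")
    keep = _ancestry_closure(analysis, terminals)
    ground_truth = build_dag([analysis.nodes[uid] for uid in keep])
    paths = sorted(
        write_archive(analysis.nodes, terminal, out_dir, spec.archive_version)
        for terminal in terminals
    )
    return paths, ground_truth


def make_overlapping_pair(
    seed: int,
) -> tuple[AnalysisSpec, AnalysisSpec, int]:
    """Two specs whose analyses share a known-size common ancestry.

    The overlap count is computed exactly by building both ground-truth
    graphs in memory and intersecting their node sets.
    """
    spec_a = AnalysisSpec(seed=seed, n_imports=1, n_actions=4,
                          multi_output_fraction=0.25)
    spec_b = AnalysisSpec(seed=seed + 7919, n_imports=1, n_actions=3,
                          shared_ancestry=spec_a)
    nodes_a = set(
        _ancestry_closure((a := _build(spec_a)), a.terminals())
    )
    b = _build(spec_b)
    nodes_b = set(_ancestry_closure(b, b.terminals()))
    return spec_a, spec_b, len(nodes_a & nodes_b)


def tamper(
    archive_path: str | Path, member_relpath: str, mode: str
) -> Path:
    """Copy an archive with exactly one alteration; the original is untouched.

    Modes: ``flip-byte`` (XOR the first byte of the member), ``delete``
    (drop the member), ``append`` (append bytes to the member, or add it
    as a new member if absent).
    """
    archive_path = Path(archive_path)
    if mode not in ("flip-byte", "delete", "append"):
        raise ValueError(f"unknown tamper mode {mode!r}")
    index = 0
    while True:
        out_path = archive_path.with_suffix(f".tampered-{index}{archive_path.suffix}")
        if not out_path.exists():
            break
        index += 1
    with zipfile.ZipFile(archive_path) as zf:
        names = [info.filename for info in zf.infolist() if not info.is_dir()]
        if member_relpath not in names and mode != "append":
            raise MissingMemberError(f"{archive_path}: no member {member_relpath!r}")
        with zipfile.ZipFile(out_path, "w", compression=zipfile.ZIP_DEFLATED) as out:
            for name in names:
                content = zf.read(name)
                if name == member_relpath:
                    if mode == "delete":
                        continue
                    if mode == "flip-byte":
                        altered = bytearray(content)
                        if not altered:
                            altered = bytearray(b"\x01")
                        else:
                            altered[0] ^= 0x01
                        content = bytes(altered)
                    elif mode == "append":
                        content += b"\n# tampered\n"
                info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
                info.compress_type = zipfile.ZIP_DEFLATED
                out.writestr(info, content)
            if mode == "append" and member_relpath not in names:
                info = zipfile.ZipInfo(member_relpath, date_time=_ZIP_DATE)
                info.compress_type = zipfile.ZIP_DEFLATED
                out.writestr(info, b"unlisted extra member\n")
    return out_path


def copy_archive(archive_path: str | Path, out_dir: str | Path) -> Path:
    """Convenience for tests: copy an archive into another directory."""
    archive_path = Path(archive_path)
    destination = Path(out_dir) / archive_path.name
    shutil.copy2(archive_path, destination)
    return destination
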