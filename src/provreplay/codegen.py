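"""Replay planning and rendering.

A replay is planned once as an ordered list of :class:`ReplayStatement`
(one per execution group, in deterministic topological order) and then
rendered per dialect:

* ``cli`` — a shell script of ``qiime <plugin> <action> --i-... --p-...
  --o-...`` command lines, booleans as ``--p-name`` / ``--p-no-name``,
  artifact files named ``<variable>.qza`` (``.qzv`` for visualizer
  outputs);
* ``api`` — a Python script of per-action calls with keyword parameters,
  outputs bound to variables.

Both dialects share one variable registry, so a result is called the same
thing in either script. Recorded parameters are replayed verbatim —
defaults and nulls included; a null renders as an explicit ``None`` in the
api dialect and is omitted (with a trailing comment) in the cli dialect,
which has no null literal. Metadata-typed parameters become placeholder
filenames plus TODO comments: recorded metadata is never silently reused.
Results that lack provenance render as comments telling the user to
supply them.
"""

from __future__ import annotations

import re
import shlex
from dataclasses import dataclass, field

from .errors import CodegenError
from .prov_dag import ProvDAG, group_by_execution
from .prov_parse import MetadataRef, ProvNode

TOOL_EXE = "qiime"
PINNED_TIMESTAMP_TOKEN = "<timestamp pinned for reproducibility>"

_SCALARS = (str, int, float, bool, type(None))


@dataclass(frozen=True)
class MetadataFile:
    """Placeholder metadata filename a user must supply at replay time."""

    path: str


@dataclass
class VariableRegistry:
    """Injective mapping from replay variable names to result UUIDs."""

    assigned: dict[str, str] = field(default_factory=dict)
    counters: dict[str, int] = field(default_factory=dict)


@dataclass
class ReplayStatement:
    """One planned replay step.

    ``kind`` is one of ``header-comment``, ``import``, ``action``,
    ``metadata-placeholder`` or ``no-provenance-comment``. Bindings map
    record names to replay variable names; ``notes`` carry dialect-neutral
    commentary (import manifests, TODO instructions).
    """

    kind: str
    execution_uuid: str | None = None
    plugin: str | None = None
    action_name: str | None = None
    input_bindings: dict[str, str] = field(default_factory=dict)
    parameter_bindings: dict[str, object] = field(default_factory=dict)
    output_bindings: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    action_type: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "action" and not (
            self.plugin and self.action_name and self.output_bindings
        ):
            raise CodegenError("action statements need plugin, action and outputs")
        if self.kind == "import" and self.input_bindings:
            raise CodegenError("import statements take no inputs")


@dataclass
class ReplayScript:
    """A rendered, self-documenting replay document."""

    dialect: str
    header: list[str]
    statements: list[ReplayStatement]
    rendered_text: str


def name_variable(output_name: str, registry: VariableRegistry, uuid: str) -> str:
    """Derive a unique, dialect-safe variable name for one result.

    Lowercase; runs of non-alphanumerics collapse to ``_``; edge
    underscores stripped; a leading digit gains an ``r_`` prefix; name
    collisions get ``_0``, ``_1``, ... suffixes.
    """
    base = re.sub(r"[^0-9a-z]+", "_", output_name.lower()).strip("_")
    if not base:
        base = "result"
    if base[0].isdigit():
        base = f"r_{base}"
    name = base
    while name in registry.assigned and registry.assigned[name] != uuid:
        index = registry.counters.get(base, 0)
        registry.counters[base] = index + 1
        name = f"{base}_{index}"
    registry.assigned[name] = uuid
    return name


def _metadata_placeholder(variable: str, param: str) -> str:
    return f"{variable}_{param}_metadata.tsv" if param != "metadata" \
        else f"{variable}_metadata.tsv"


def plan_replay(dag: ProvDAG) -> list[ReplayStatement]:
    """Plan the replay: one statement per execution group.

    Guarantees def-before-use: every input binding names a variable
    introduced by an earlier statement (including no-provenance
    placeholders). Groups whose parameters include metadata references
    are preceded by a metadata-placeholder statement.
    """
    registry = VariableRegistry()
    var_of: dict[str, str] = {}
    statements: list[ReplayStatement] = []
    for exec_uuid, members in group_by_execution(dag):
        record = members[0].action
        if record is None:
            node = members[0]
            variable = name_variable(_stub_base(node), registry, node.result_uuid)
            var_of[node.result_uuid] = variable
            statements.append(
                ReplayStatement(
                    kind="no-provenance-comment",
                    output_bindings={"result": variable},
                    notes=[
                        f"result {node.result_uuid} has no recorded provenance",
                        f"TODO: obtain this result and save it as {variable}.qza "
                        "before running the steps below",
                    ],
                )
            )
            continue

        outputs: dict[str, str] = {}
        for member in members:
            assert member.action is not None
            variable = name_variable(
                member.action.output_name, registry, member.result_uuid
            )
            var_of[member.result_uuid] = variable
            outputs[member.action.output_name] = variable
        first_var = next(iter(outputs.values()))

        if record.action_type == "import":
            notes = [
                f"import manifest: {entry.filename} (md5 {entry.md5sum})"
                for entry in record.import_manifest
            ]
            semantic_type = (
                members[0].metadata.semantic_type if members[0].metadata else "Artifact"
            )
            statements.append(
                ReplayStatement(
                    kind="import",
                    execution_uuid=exec_uuid,
                    parameter_bindings={"type": semantic_type},
                    output_bindings=outputs,
                    notes=notes,
                    action_type="import",
                )
            )
            continue

        metadata_params = [
            name for name, value in record.parameters.items()
            if isinstance(value, MetadataRef)
        ]
        if metadata_params:
            statements.append(
                ReplayStatement(
                    kind="metadata-placeholder",
                    execution_uuid=exec_uuid,
                    notes=[
                        f"TODO: supply {_metadata_placeholder(first_var, name)} "
                        f"(recorded as {record.parameters[name].filename!r} "
                        f"for parameter {name!r})"
                        for name in metadata_params
                    ],
                )
            )

        input_bindings = {
            name: var_of[input_uuid]
            for name, input_uuid in record.inputs.items()
            if input_uuid is not None
        }
        null_inputs = [name for name, value in record.inputs.items() if value is None]
        parameters = {
            name: (
                MetadataFile(_metadata_placeholder(first_var, name))
                if isinstance(value, MetadataRef)
                else value
            )
            for name, value in record.parameters.items()
        }
        notes = [f"optional input {name!r} was not provided" for name in null_inputs]
        statements.append(
            ReplayStatement(
                kind="action",
                execution_uuid=exec_uuid,
                plugin=record.plugin,
                action_name=record.action_name,
                input_bindings=input_bindings,
                parameter_bindings=parameters,
                output_bindings=outputs,
                notes=notes,
                action_type=record.action_type,
            )
        )
    return statements


def _stub_base(node: ProvNode) -> str:
    if node.metadata is not None:
        return node.metadata.semantic_type
    return f"r_{node.result_uuid.split('-')[0]}"


def build_header(
    sources: list[str], tool_version: str, timestamp: str
) -> list[str]:
    """Self-documentation lines shared by both dialects (no comment prefix)."""
    unique_sources = list(dict.fromkeys(sources))
    if not unique_sources:
        raise CodegenError("a replay header needs at least one source result")
    return [
        f"Replay document generated by provreplay {tool_version}",
        f"generated at: {timestamp}",
        f"generated from result(s): {', '.join(unique_sources)}",
        "",
        "This script was reconstructed from recorded data provenance.",
        "Usage instructions:",
        "  1. Install the analysis platform and the plugin versions noted in",
        "     the recorded provenance of the source results.",
        "  2. Supply every input file marked TODO (imported data and any",
        "     *_metadata.tsv placeholder files) next to this script.",
        "  3. Review the commands below; parameter values are replayed",
        "     verbatim from the recorded provenance, including defaults.",
        "  4. Execute this script from its own directory.",
    ]


# --- cli dialect -----------------------------------------------------------


def _kebab(name: str) -> str:
    return name.replace("_", "-")


def _ext(statement: ReplayStatement) -> str:
    return ".qzv" if statement.action_type == "visualizer" else ".qza"


def _cli_scalar(value: object) -> str:
    if isinstance(value, str):
        return shlex.quote(value)
    if isinstance(value, bool) or value is None:
        raise CodegenError("booleans/nulls are handled at the flag level")
    if isinstance(value, (int, float)):
        return repr(value)
    raise CodegenError(f"cannot render parameter value {value!r} in cli dialect")


def _cli_command(statement: ReplayStatement) -> str:
    tokens: list[str] = [TOOL_EXE]
    trailing: list[str] = []
    if statement.kind == "import":
        tokens += ["tools", "import"]
        tokens += ["--type", shlex.quote(str(statement.parameter_bindings["type"]))]
        tokens += ["--input-path", "TODO-import-path"]
        ((_, variable),) = statement.output_bindings.items()
        tokens += ["--output-path", f"{variable}{_ext(statement)}"]
        return " ".join(tokens)
    tokens += [statement.plugin, statement.action_name]
    for name, variable in statement.input_bindings.items():
        tokens += [f"--i-{_kebab(name)}", f"{variable}.qza"]
    for name, value in statement.parameter_bindings.items():
        flag = _kebab(name)
        if value is None:
            trailing.append(f"--p-{flag} left at its recorded default (null)")
        elif isinstance(value, bool):
            tokens.append(f"--p-{flag}" if value else f"--p-no-{flag}")
        elif isinstance(value, MetadataFile):
            tokens += [f"--m-{flag}-file", value.path]
        elif isinstance(value, list):
            tokens.append(f"--p-{flag}")
            tokens += [_cli_scalar(item) for item in value]
        else:
            tokens += [f"--p-{flag}", _cli_scalar(value)]
    for name, variable in statement.output_bindings.items():
        tokens += [f"--o-{_kebab(name)}", f"{variable}{_ext(statement)}"]
    command = " ".join(tokens)
    if trailing:
        command += "  # " + "; ".join(trailing)
    return command


def render_cli(statements: list[ReplayStatement], header: list[str]) -> ReplayScript:
    """Render the shell dialect: one command line per action/import."""
    lines = ["#!/usr/bin/env bash"]
    lines += [f"# {line}".rstrip() for line in header]
    lines.append("")
    for statement in statements:
        if statement.kind in ("no-provenance-comment", "metadata-placeholder"):
            lines += [f"# {note}" for note in statement.notes]
            lines.append("")
            continue
        if statement.kind == "header-comment":
            lines += [f"# {note}" for note in statement.notes]
            continue
        label = (
            "import"
            if statement.kind == "import"
            else f"{statement.plugin} {statement.action_name}"
        )
        lines.append(f"# {label} (execution {statement.execution_uuid})")
        lines += [f"# {note}" for note in statement.notes]
        lines.append(_cli_command(statement))
        lines.append("")
    text = "\n".join(lines).rstrip("\n") + "\n"
    return ReplayScript(
        dialect="cli", header=list(header), statements=statements, rendered_text=text
    )


# --- api dialect -----------------------------------------------------------


def _snake(name: str) -> str:
    return name.replace("-", "_")


def _py_value(value: object) -> str:
    if isinstance(value, _SCALARS):
        return repr(value)
    if isinstance(value, list):
        return "[" + ", ".join(_py_value(item) for item in value) + "]"
    raise CodegenError(f"cannot render parameter value {value!r} in api dialect")


def render_api(statements: list[ReplayStatement], header: list[str]) -> ReplayScript:
    """Render the Python dialect: one call per action, outputs unpacked."""
    lines = ["#!/usr/bin/env python"]
    lines.append('"""')
    lines += [line.rstrip() for line in header]
    lines.append('"""')
    lines.append("")
    lines.append("import qiime2")
    plugins = sorted(
        {statement.plugin for statement in statements if statement.kind == "action"}
    )
    for plugin in plugins:
        alias = _snake(plugin)
        lines.append(f"from qiime2.plugins.{alias} import actions as {alias}_actions")
    lines.append("")

    result_counter = 0
    for statement in statements:
        if statement.kind in ("no-provenance-comment", "metadata-placeholder",
                              "header-comment"):
            lines += [f"# {note}" for note in statement.notes]
            if statement.kind == "no-provenance-comment":
                variable = statement.output_bindings["result"]
                lines.append(
                    f"{variable} = qiime2.Artifact.load({variable + '.qza'!r})  # TODO"
                )
            lines.append("")
            continue
        lines.append(f"# execution {statement.execution_uuid}")
        lines += [f"# {note}" for note in statement.notes]
        if statement.kind == "import":
            ((_, variable),) = statement.output_bindings.items()
            semantic_type = statement.parameter_bindings["type"]
            lines.append(
                f"{variable} = qiime2.Artifact.import_data("
                f"{semantic_type!r}, 'TODO-import-path')"
            )
            lines.append("")
            continue
        arguments = []
        for name, variable in statement.input_bindings.items():
            arguments.append(f"{_snake(name)}={variable}")
        for name, value in statement.parameter_bindings.items():
            if isinstance(value, MetadataFile):
                arguments.append(
                    f"{_snake(name)}=qiime2.Metadata.load({value.path!r})"
                )
            else:
                arguments.append(f"{_snake(name)}={_py_value(value)}")
        call = (
            f"results_{result_counter} = "
            f"{_snake(statement.plugin)}_actions.{_snake(statement.action_name)}"
            f"({', '.join(arguments)})"
        )
        lines.append(call)
        for output_name, variable in statement.output_bindings.items():
            lines.append(f"{variable} = results_{result_counter}.{_snake(output_name)}")
        result_counter += 1
        lines.append("")
    text = "\n".join(lines).rstrip("\n") + "\n"
    return ReplayScript(
        dialect="api", header=list(header), statements=statements, rendered_text=text
    )


def render(
    statements: list[ReplayStatement], header: list[str], dialect: str
) -> ReplayScript:
    if dialect == "cli":
        return render_cli(statements, header)
    if dialect == "api":
        return render_api(statements, header)
    raise CodegenError(f"unknown dialect {dialect!r}")
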