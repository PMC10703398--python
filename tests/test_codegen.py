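import ast
import re
import shlex

import pytest

from provreplay import (
    AnalysisSpec,
    VariableRegistry,
    build_dag,
    build_header,
    discover_archives,
    name_variable,
    parse_provenance_tree,
    plan_replay,
    render_api,
    render_cli,
    simulate_analysis,
    union,
)
from provreplay.codegen import PINNED_TIMESTAMP_TOKEN
from provreplay.prov_parse import MetadataRef


def _uuid(n):
    return f"{n:0>8}-0000-4000-8000-000000000000"


def scan_cli_def_before_use(text: str) -> bool:
    """Brute-force def-before-use over the shell dialect."""
    defined = set()
    for line in text.splitlines():
        for match in re.finditer(r"save it as (\w+)\.qza", line):
            defined.add(match.group(1))
        if line.startswith("#") or not line.strip():
            continue
        tokens = shlex.split(line.split("  #", 1)[0])
        used, produced = [], []
        for flag, value in zip(tokens, tokens[1:]):
            if flag.startswith("--i-"):
                used.append(value.rsplit(".", 1)[0])
            elif flag.startswith("--o-") or flag == "--output-path":
                produced.append(value.rsplit(".", 1)[0])
        if any(variable not in defined for variable in used):
            return False
        defined.update(produced)
    return True


def scan_api_def_before_use(text: str) -> bool:
    """Brute-force def-before-use over the Python dialect via the AST."""
    module = ast.parse(text)
    defined = {"qiime2"}
    for statement in module.body:
        if isinstance(statement, (ast.Import, ast.ImportFrom)):
            for alias in statement.names:
                defined.add(alias.asname or alias.name)
            continue
        loaded = {
            node.id
            for node in ast.walk(statement)
            if isinstance(node, ast.Name) and isinstance(node.ctx, ast.Load)
        }
        if loaded - defined:
            return False
        for node in ast.walk(statement):
            if isinstance(node, ast.Name) and isinstance(node.ctx, ast.Store):
                defined.add(node.id)
    return True


@pytest.mark.parametrize(
    ("raw", "expected"),
    [
        ("table", "table"),
        ("Taxa Bar-Plot!", "taxa_bar_plot"),
        ("__x__", "x"),
        ("42fold", "r_42fold"),
        ("???", "result"),
    ],
)
def test_variable_sanitization(raw, expected):
    assert name_variable(raw, VariableRegistry(), _uuid("1")) == expected


def test_variable_dedup_by_uuid():
    registry = VariableRegistry()
    assert name_variable("table", registry, _uuid("1")) == "table"
    assert name_variable("table", registry, _uuid("2")) == "table_0"
    assert name_variable("table", registry, _uuid("3")) == "table_1"
    # same uuid asks again -> same name, registry stays injective
    assert name_variable("table", registry, _uuid("1")) == "table"
    assert len(set(registry.assigned)) == len(registry.assigned)


def test_header_contract():
    sources = [_uuid("a"), _uuid("b"), _uuid("a")]
    header = build_header(sources, "0.1.0", PINNED_TIMESTAMP_TOKEN)
    joined = "\n".join(header)
    assert joined.count(_uuid("a")) == 1 and joined.count(_uuid("b")) == 1
    numbered = [line for line in header if re.match(r"\s*\d+\.", line)]
    assert len(numbered) >= 3
    assert "verbatim" in joined  # replayed-parameters caveat


@pytest.fixture(scope="module")
def planned(small_dag_module):
    dag = small_dag_module
    statements = plan_replay(dag)
    header = build_header([_uuid("f")], "0.1.0", PINNED_TIMESTAMP_TOKEN)
    return dag, statements, header


@pytest.fixture(scope="module")
def small_dag_module(tmp_path_factory):
    out = tmp_path_factory.mktemp("codegen")
    simulate_analysis(
        AnalysisSpec(seed=13, n_imports=2, n_actions=6, metadata_param_fraction=0.5),
        out,
    )
    archives = discover_archives([out])
    return union([build_dag(parse_provenance_tree(a)) for a in archives])


def test_plan_is_ordered_and_complete(planned):
    dag, statements, _ = planned
    action_like = [s for s in statements if s.kind in ("import", "action")]
    executions = {
        node.action.execution_uuid
        for node in dag.nodes.values()
        if node.action is not None
    }
    assert len(action_like) == len(executions)
    # every statement's inputs refer to variables defined earlier
    defined = set()
    for statement in statements:
        assert set(statement.input_bindings.values()) <= defined
        defined.update(statement.output_bindings.values())


def test_rendered_scripts_are_deterministic_and_well_formed(planned):
    _, statements, header = planned
    shell = render_cli(statements, header)
    assert shell.rendered_text == render_cli(statements, header).rendered_text
    api = render_api(statements, header)
    assert api.rendered_text == render_api(statements, header).rendered_text
    assert scan_cli_def_before_use(shell.rendered_text)
    assert scan_api_def_before_use(api.rendered_text)
    for line in shell.rendered_text.splitlines()[1:]:
        if line in ("", "#!/usr/bin/env bash"):
            continue
        assert line.startswith("#") or line.startswith("qiime ")


def test_parameter_faithfulness_including_defaults_and_nulls(planned):
    dag, statements, header = planned
    shell_lines = render_cli(statements, header).rendered_text.splitlines()
    api_text = render_api(statements, header).rendered_text
    by_exec = {s.execution_uuid: s for s in statements if s.kind == "action"}
    for node in dag.nodes.values():
        record = node.action
        if record is None or record.action_type == "import":
            continue
        statement = by_exec[record.execution_uuid]
        command = next(
            line for line in shell_lines
            if line.startswith("qiime ")
            and all(
                f" {variable}." in f"{line} "
                for variable in statement.output_bindings.values()
            )
        )
        for name, value in record.parameters.items():
            kebab = name.replace("_", "-")
            assert f"-{kebab}" in command  # --p-, --p-no- or --m- spelling
            assert f"{name}=" in api_text
            if value is None:
                assert f"{name}=None" in api_text
            elif isinstance(value, bool):
                token = f"--p-{kebab}" if value else f"--p-no-{kebab}"
                assert token in command.split()


def test_boolean_flags_carry_no_value_token(planned):
    _, statements, header = planned
    shell = render_cli(statements, header).rendered_text
    for match in re.finditer(r"(--p-[\w-]+)( \S+)?", shell):
        flag = match.group(1)
        # a boolean flag is never followed by the literal words True/False
        assert match.group(2) not in (" True", " False"), flag


def test_no_provenance_nodes_render_as_comments():
    from provreplay.archive_model import ResultMetadata
    from provreplay.prov_parse import (
        ActionRecord,
        EnvironmentRecord,
        ImportManifestEntry,
        ProvNode,
    )

    env = EnvironmentRecord("p", "l", "1.0", {"demux": "1.0"})
    stub_input = _uuid("aa")
    consumer = _uuid("bb")
    record = ActionRecord(
        execution_uuid=consumer,
        action_type="method",
        plugin="demux",
        action_name="emp-single",
        inputs={"seqs": stub_input},
        parameters={"rev_comp_barcodes": False},
        output_name="per_sample_sequences",
        start_time="2023-05-01T12:00:00+00:00",
        end_time="2023-05-01T12:01:00+00:00",
    )
    node = ProvNode(consumer, ResultMetadata(consumer, "T", "F"), record, env, True)
    dag = build_dag([node])
    statements = plan_replay(dag)
    kinds = [statement.kind for statement in statements]
    assert kinds == ["no-provenance-comment", "action"]
    placeholder = statements[0].output_bindings["result"]
    assert statements[1].input_bindings == {"seqs": placeholder}
    shell = render_cli(statements, build_header([consumer], "0", "t"))
    assert "no recorded provenance" in shell.rendered_text
    assert scan_cli_def_before_use(shell.rendered_text)


def test_metadata_parameters_become_placeholders(planned):
    dag, statements, header = planned
    recorded = sum(
        1
        for exec_uuid in {
            n.action.execution_uuid
            for n in dag.nodes.values()
            if n.action is not None
            and any(isinstance(v, MetadataRef) for v in n.action.parameters.values())
        }
        if exec_uuid
    )
    placeholders = [s for s in statements if s.kind == "metadata-placeholder"]
    assert len(placeholders) == recorded
    shell = render_cli(statements, header).rendered_text
    assert shell.count("_metadata.tsv") >= recorded
    assert "sample-metadata.tsv" in shell  # recorded filename surfaced in the TODO
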