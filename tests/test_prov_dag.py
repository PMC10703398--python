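import random

import pytest

from provreplay import (
    AnalysisSpec,
    ancestry,
    build_dag,
    export_dot,
    group_by_execution,
    simulate_analysis,
    topological_order,
    union,
)
from provreplay.archive_model import ResultMetadata
from provreplay.errors import ConflictError, CorruptProvenanceError, MissingNodeError
from provreplay.prov_parse import (
    ActionRecord,
    EnvironmentRecord,
    ImportManifestEntry,
    ProvNode,
)


def parse_union(archives):
    from provreplay import build_dag, parse_provenance_tree, union

    return union([build_dag(parse_provenance_tree(a)) for a in archives])

_ENV = EnvironmentRecord(
    platform="p", language="l", framework_version="1.0",
    plugin_versions={"demux": "1.0"},
)


def _node(uuid, inputs=None, action_type="method", start="2023-05-01T12:00:00+00:00",
          parameters=None):
    record = ActionRecord(
        execution_uuid=uuid,
        action_type=action_type,
        plugin=None if action_type == "import" else "demux",
        action_name=None if action_type == "import" else "emp-single",
        inputs=inputs or {},
        parameters=parameters or {},
        output_name="out",
        start_time=start,
        end_time=start,
        import_manifest=(
            () if action_type != "import"
            else (ImportManifestEntry("f", "d41d8cd98f00b204e9800998ecf8427e"),)
        ),
    )
    return ProvNode(
        result_uuid=uuid,
        metadata=ResultMetadata(uuid, "T", "F"),
        action=record,
        environment=_ENV,
        has_provenance=True,
    )


def _uuid(prefix):
    return f"{prefix:0>8}-0000-4000-8000-000000000000"


U1, U2, U3 = _uuid("a1"), _uuid("b2"), _uuid("c3")


def test_chain_edges_and_terminals():
    dag = build_dag([
        _node(U1, action_type="import"),
        _node(U2, inputs={"seqs": U1}),
        _node(U3, inputs={"seqs": U2}, action_type="visualizer"),
    ])
    assert dag.edges == {(U1, U2), (U2, U3)}
    assert dag.terminal_uuids == {U3}
    single = build_dag([_node(U1, action_type="import")])
    assert len(single) == 1 and single.edges == set() and single.terminal_uuids == {U1}


def test_cycle_is_corrupt_provenance():
    with pytest.raises(CorruptProvenanceError, match="cycle"):
        build_dag([_node(U1, inputs={"x": U2}), _node(U2, inputs={"x": U1})])


def test_unknown_inputs_become_stub_nodes():
    dag = build_dag([_node(U2, inputs={"seqs": U1})])
    assert not dag.node(U1).has_provenance
    assert dag.edges == {(U1, U2)}


def test_union_idempotent_commutative_and_disjoint(tmp_path):
    paths_a, _ = simulate_analysis(AnalysisSpec(seed=21, n_imports=1, n_actions=3),
                                   tmp_path / "a")
    paths_b, _ = simulate_analysis(AnalysisSpec(seed=22, n_imports=1, n_actions=3),
                                   tmp_path / "b")
    from provreplay import discover_archives

    dag_a = parse_union(discover_archives([tmp_path / "a"]))
    dag_b = parse_union(discover_archives([tmp_path / "b"]))
    assert union([dag_a, dag_a]).nodes == dag_a.nodes
    assert union([dag_a, dag_a]).edges == dag_a.edges
    ab, ba = union([dag_a, dag_b]), union([dag_b, dag_a])
    assert ab.nodes == ba.nodes and ab.edges == ba.edges
    assert len(ab) == len(dag_a) + len(dag_b)  # disjoint seeds share nothing


def test_union_rejects_conflicting_records_for_same_uuid():
    one = build_dag([_node(U1, action_type="import")])
    other = build_dag([
        _node(U1, action_type="import", parameters={}, start="2023-05-02T12:00:00+00:00")
    ])
    with pytest.raises(ConflictError, match="immutable"):
        union([one, other])


def test_full_provenance_replaces_stub_in_union():
    with_stub = build_dag([_node(U2, inputs={"seqs": U1})])
    full = build_dag([_node(U1, action_type="import")])
    merged = union([with_stub, full])
    assert merged.node(U1).has_provenance


def test_ancestry_matches_reverse_reachability_oracle(tmp_path):
    rng = random.Random(0)
    for seed in rng.sample(range(10_000), 5):
        directory = tmp_path / str(seed)
        simulate_analysis(AnalysisSpec(seed=seed, n_imports=2, n_actions=5), directory)
        from provreplay import discover_archives

        dag = parse_union(discover_archives([directory]))
        reverse: dict[str, set[str]] = {}
        for producer, consumer in dag.edges:
            reverse.setdefault(consumer, set()).add(producer)
        for uuid in dag.nodes:
            # independent oracle: DFS over reversed edges
            seen, stack = set(), [uuid]
            while stack:
                current = stack.pop()
                if current in seen:
                    continue
                seen.add(current)
                stack.extend(reverse.get(current, ()))
            sub = ancestry(dag, uuid)
            assert set(sub.nodes) == seen
            assert sub.terminal_uuids == {uuid}
    with pytest.raises(MissingNodeError):
        ancestry(dag, _uuid("ff"))


def test_topological_order_respects_edges_and_tie_break(small_dag):
    order = topological_order(small_dag)
    position = {uuid: index for index, uuid in enumerate(order)}
    for producer, consumer in small_dag.edges:
        assert position[producer] < position[consumer]
    # equal timestamps fall back to ascending uuid
    tie = build_dag([_node(U2, action_type="import"), _node(U1, action_type="import")])
    assert topological_order(tie) == sorted([U1, U2])


def test_group_by_execution_counts_and_multi_output(small_dag):
    groups = group_by_execution(small_dag)
    distinct = {
        node.action.execution_uuid
        for node in small_dag.nodes.values()
        if node.action is not None
    }
    no_prov = sum(1 for n in small_dag.nodes.values() if not n.has_provenance)
    assert len(groups) == len(distinct) + no_prov
    for exec_uuid, members in groups:
        if exec_uuid is None:
            assert len(members) == 1
        else:
            assert len({m.action.execution_uuid for m in members}) == 1


def test_group_conflict_detection():
    shared_exec = _uuid("e5")
    node_a = _node(U1, action_type="import")
    record = node_a.action.__class__(
        **{**node_a.action.__dict__, "execution_uuid": shared_exec}
    )
    conflicting = node_a.action.__class__(
        **{**node_a.action.__dict__, "execution_uuid": shared_exec,
           "parameters": {"x": 1}}
    )
    nodes = [
        ProvNode(U1, ResultMetadata(U1, "T", "F"), record, _ENV, True),
        ProvNode(U2, ResultMetadata(U2, "T", "F"), conflicting, _ENV, True),
    ]
    with pytest.raises(ConflictError, match="disagree"):
        group_by_execution(build_dag(nodes))


def test_dot_export_labels_execution_groups(small_dag):
    dot = export_dot(small_dag)
    assert dot.startswith("digraph provenance")
    labels = {
        f"{node.action.plugin} : {node.action.action_name}"
        for node in small_dag.nodes.values()
        if node.action is not None and node.action.action_type != "import"
    }
    for label in labels:
        assert label in dot
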