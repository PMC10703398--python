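"""Provenance DAG: construction, union, subsetting, ordering.

Results are the nodes (keyed by result UUID); a directed edge runs from
each input result to the result it helped produce. Actions are not a
separate node class — an execution that emitted several results is
recovered by grouping nodes on their shared execution UUID. Input UUIDs
with no parsed record become stub nodes (``has_provenance=False``) so
partial archives degrade gracefully instead of failing.
"""

from __future__ import annotations

import heapq
from datetime import datetime, timezone
from typing import Iterable

import networkx as nx

from .errors import ConflictError, CorruptProvenanceError, MissingNodeError
from .prov_parse import ProvNode

_EPOCH = datetime.min.replace(tzinfo=timezone.utc)


class ProvDAG:
    """Directed acyclic graph of results and the executions behind them."""

    def __init__(self, graph: nx.DiGraph) -> None:
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise CorruptProvenanceError(f"provenance contains a cycle: {cycle}")
        self._graph = graph

    @property
    def nodes(self) -> dict[str, ProvNode]:
        return {uuid: data["node"] for uuid, data in self._graph.nodes(data=True)}

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._graph.edges())

    @property
    def terminal_uuids(self) -> set[str]:
        return {uuid for uuid, deg in self._graph.out_degree() if deg == 0}

    def node(self, uuid: str) -> ProvNode:
        try:
            return self._graph.nodes[uuid]["node"]
        except KeyError:
            raise MissingNodeError(f"no node {uuid} in DAG") from None

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def __contains__(self, uuid: str) -> bool:
        return uuid in self._graph


def _stub(uuid: str) -> ProvNode:
    return ProvNode(result_uuid=uuid)


def build_dag(nodes: Iterable[ProvNode]) -> ProvDAG:
    """Build a DAG from parsed nodes; acyclicity is verified.

    One edge is added per non-null ``(input uuid -> node uuid)`` pair in
    each action record; inputs naming unknown UUIDs become stub nodes.
    """
    graph = nx.DiGraph()
    for node in nodes:
        if node.result_uuid in graph:
            raise ConflictError(f"duplicate result uuid {node.result_uuid}")
        graph.add_node(node.result_uuid, node=node)
    for uuid, data in list(graph.nodes(data=True)):
        record = data["node"].action
        if record is None:
            continue
        for input_uuid in record.inputs.values():
            if input_uuid is None:
                continue
            if input_uuid not in graph:
                graph.add_node(input_uuid, node=_stub(input_uuid))
            graph.add_edge(input_uuid, uuid)
    return ProvDAG(graph)


def _merge_nodes(first: ProvNode, second: ProvNode) -> ProvNode:
    """First-parsed record wins; full provenance always beats a stub."""
    if first.has_provenance and second.has_provenance:
        assert first.action is not None and second.action is not None
        if not first.action.same_execution_as(second.action):
            raise ConflictError(
                f"conflicting action records for immutable result {first.result_uuid}"
            )
        return first
    return first if first.has_provenance else second


def union(dags: list[ProvDAG]) -> ProvDAG:
    """Merge DAGs over shared result UUIDs; shared ancestry appears once."""
    if not dags:
        raise ValueError("union requires at least one DAG")
    graph = nx.DiGraph()
    for dag in dags:
        for uuid, node in dag.nodes.items():
            if uuid in graph:
                graph.nodes[uuid]["node"] = _merge_nodes(graph.nodes[uuid]["node"], node)
            else:
                graph.add_node(uuid, node=node)
        graph.add_edges_from(dag.edges)
    return ProvDAG(graph)


def ancestry(dag: ProvDAG, uuid: str) -> ProvDAG:
    """Induced sub-DAG of *uuid* and all its transitive producers."""
    if uuid not in dag:
        raise MissingNodeError(f"no node {uuid} in DAG")
    keep = nx.ancestors(dag._graph, uuid) | {uuid}
    return ProvDAG(dag._graph.subgraph(keep).copy())


def _order_key(node: ProvNode) -> tuple[datetime, str]:
    instant = node.action.start_instant if node.action is not None else _EPOCH
    return (instant, node.result_uuid)


def topological_order(dag: ProvDAG) -> list[str]:
    """Deterministic topological order.

    Producers precede consumers; ties are broken by ascending
    (start time, result uuid) so output is byte-stable across runs and
    across input orderings.
    """
    graph = dag._graph
    indegree = dict(graph.in_degree())
    ready = [
        (_order_key(graph.nodes[uuid]["node"]), uuid)
        for uuid, deg in indegree.items()
        if deg == 0
    ]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        _, uuid = heapq.heappop(ready)
        order.append(uuid)
        for successor in graph.successors(uuid):
            indegree[successor] -= 1
            if indegree[successor] == 0:
                heapq.heappush(
                    ready, (_order_key(graph.nodes[successor]["node"]), successor)
                )
    return order


def group_by_execution(dag: ProvDAG) -> list[tuple[str | None, list[ProvNode]]]:
    """Group nodes sharing an execution UUID, in replay order.

    One action run that produced several results appears as one group so
    replay emits it once. Nodes without provenance form singleton groups
    keyed ``None``. Group order follows the topological position of each
    group's earliest member; members keep topological order within the
    group.
    """
    order = topological_order(dag)
    groups: dict[tuple, list[ProvNode]] = {}
    sequence: list[tuple] = []
    for uuid in order:
        node = dag.node(uuid)
        key = (
            ("exec", node.action.execution_uuid)
            if node.action is not None
            else ("noprov", uuid)
        )
        if key not in groups:
            groups[key] = []
            sequence.append(key)
        groups[key].append(node)
    out: list[tuple[str | None, list[ProvNode]]] = []
    for key in sequence:
        members = groups[key]
        first = members[0]
        for other in members[1:]:
            assert first.action is not None and other.action is not None
            if not first.action.same_execution_as(other.action):
                raise ConflictError(
                    f"nodes sharing execution {key[1]} disagree on the action record"
                )
        out.append((key[1] if key[0] == "exec" else None, members))
    return out


def export_dot(dag: ProvDAG) -> str:
    """Render the DAG in DOT, one box per execution group.

    Boxes are labeled ``plugin : action`` (or ``import``); edges between
    groups are labeled with the result that carried the dependency.
    """
    groups = group_by_execution(dag)
    group_of: dict[str, int] = {}
    lines = ["digraph provenance {", "  rankdir=TB;", "  node [shape=box];"]
    for index, (exec_uuid, members) in enumerate(groups):
        for member in members:
            group_of[member.result_uuid] = index
        record = members[0].action
        if record is None:
            label = f"(no provenance)\\n{members[0].result_uuid[:8]}"
        elif record.action_type == "import":
            label = f"import\\n{record.output_name}"
        else:
            label = f"{record.plugin} : {record.action_name}"
        lines.append(f'  g{index} [label="{label}"];')
    for producer, consumer in sorted(dag.edges):
        src, dst = group_of[producer], group_of[consumer]
        lines.append(f'  g{src} -> g{dst} [label="{producer[:8]}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
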