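"""Two-level representation of one organism's metabolism.

The *functional* level keeps, per reference pathway, the multiset of
reaction accessions found in the organism's KGML file. The *structural*
level is a graph whose nodes are the organism's pathways and whose
edges join pathways sharing at least one non-ubiquitous compound.

The structural graph is stored as a square integer adjacency matrix
over the whole configured pathway universe, in a fixed (ascending
pathway-number) order so that matrices of different organisms are
position-aligned. Off-diagonal entries hold the number of shared
non-ubiquitous compounds. The diagonal encodes pathway status:

* ``-1``  — pathway absent from this organism (no KGML file);
* ``0``   — pathway present but isolated (no shared compounds);
* ``k>0`` — pathway present with exactly k neighbouring pathways.

Only presence of an edge (>= 1 shared compound) matters for the
structural similarity index; the stored count is informative and is
carried as an edge weight on exports.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional

import networkx as nx
import numpy as np

from .ids import DEFAULT_UBIQUITOUS, validate_pathway_number
from .kgml_io import PathwayRecord

__all__ = [
    "PathwayStatus",
    "TwoLevelNetwork",
    "build_network",
    "edge_set",
    "export_graph",
    "to_networkx",
    "matrix_to_tsv",
]


class PathwayStatus(enum.Enum):
    """Presence classification of a reference pathway in one organism."""

    ABSENT = "absent"      # no KGML file
    PHYSICAL = "physical"  # KGML exists, zero reactions (membrane mechanism)
    REACTION = "reaction"  # KGML exists with >= 1 reaction


@dataclass(frozen=True)
class TwoLevelNetwork:
    org_code: str
    universe: tuple[str, ...]
    status: Mapping[str, PathwayStatus]
    reactions: Mapping[str, Mapping[str, int]]
    filtered_compounds: Mapping[str, frozenset[str]]
    matrix: np.ndarray
    titles: Mapping[str, str]

    def index_of(self, pathway_number: str) -> int:
        return self.universe.index(pathway_number)

    def is_present(self, pathway_number: str) -> bool:
        return self.status[pathway_number] is not PathwayStatus.ABSENT

    @property
    def present_pathways(self) -> tuple[str, ...]:
        return tuple(p for p in self.universe if self.is_present(p))


def build_network(
    records: Mapping[str, Optional[PathwayRecord]],
    universe: list[str] | tuple[str, ...],
    ubiquitous: frozenset[str] | set[str] = DEFAULT_UBIQUITOUS,
    org_code: str = "",
) -> TwoLevelNetwork:
    """Assemble the two-level network of one organism.

    Parameters
    ----------
    records
        Map from pathway number to parsed record, or ``None`` for an
        absent pathway (as produced by :func:`metnet.kgml_io.load_organism`).
    universe
        Reference pathways under consideration; duplicate-free. Stored
        sorted ascending so every organism's matrix is position-aligned.
    ubiquitous
        Compound accessions removed before computing shared-compound
        edges.
    org_code
        Organism code; inferred from the first record when omitted.
    """
    ordered = tuple(sorted(validate_pathway_number(n) for n in universe))
    if not ordered:
        raise ValueError("universe must be non-empty")
    if len(set(ordered)) != len(ordered):
        raise ValueError("universe contains duplicate pathway numbers")
    extra = set(records) - set(ordered)
    if extra:
        raise ValueError(f"records outside the universe: {sorted(extra)}")

    ubiquitous = frozenset(ubiquitous)
    status: dict[str, PathwayStatus] = {}
    reactions: dict[str, dict[str, int]] = {}
    compounds: dict[str, frozenset[str]] = {}
    titles: dict[str, str] = {}
    for number in ordered:
        record = records.get(number)
        if record is None:
            status[number] = PathwayStatus.ABSENT
            reactions[number] = {}
            compounds[number] = frozenset()
            titles[number] = ""
        else:
            if not org_code:
                org_code = record.org_code
            status[number] = (
                PathwayStatus.PHYSICAL if record.is_physical else PathwayStatus.REACTION
            )
            reactions[number] = dict(record.reaction_occurrences)
            compounds[number] = frozenset(record.compound_set) - ubiquitous
            titles[number] = record.title

    n = len(ordered)
    matrix = np.zeros((n, n), dtype=int)
    for i in range(n):
        if status[ordered[i]] is PathwayStatus.ABSENT:
            continue
        for j in range(i + 1, n):
            if status[ordered[j]] is PathwayStatus.ABSENT:
                continue
            shared = len(compounds[ordered[i]] & compounds[ordered[j]])
            matrix[i, j] = matrix[j, i] = shared
    for i in range(n):
        if status[ordered[i]] is PathwayStatus.ABSENT:
            matrix[i, i] = -1
        else:
            row = matrix[i]
            matrix[i, i] = int(np.count_nonzero(np.delete(row, i) > 0))

    return TwoLevelNetwork(
        org_code=org_code,
        universe=ordered,
        status=status,
        reactions=reactions,
        filtered_compounds=compounds,
        matrix=matrix,
        titles=titles,
    )


def edge_set(net: TwoLevelNetwork, p: str) -> frozenset[str]:
    """Neighbours of pathway ``p`` in the structural graph.

    Edges incident to a node are identified by their far endpoint, so
    two organisms' edge sets for the same pathway are directly
    comparable. Raises on an absent pathway: status must be branched
    on first (an absent node has no structural neighbourhood).
    """
    if not net.is_present(p):
        raise ValueError(f"pathway {p} is absent from organism {net.org_code!r}")
    i = net.index_of(p)
    return frozenset(
        q for j, q in enumerate(net.universe) if j != i and net.matrix[i, j] > 0
    )


def to_networkx(net: TwoLevelNetwork) -> nx.Graph:
    """Structural graph as a networkx Graph over present pathways.

    Node attributes: ``title``, ``status``; edge attribute ``weight``
    holds the shared non-ubiquitous compound count. Insertion order is
    deterministic (universe order), so serializations are stable.
    """
    graph = nx.Graph(org_code=net.org_code)
    for p in net.present_pathways:
        graph.add_node(p, title=net.titles[p], status=net.status[p].value)
    for i, p in enumerate(net.universe):
        if not net.is_present(p):
            continue
        for j in range(i + 1, len(net.universe)):
            q = net.universe[j]
            if net.matrix[i, j] > 0:
                graph.add_edge(p, q, weight=int(net.matrix[i, j]))
    return graph


def _dot_escape(value: str) -> str:
    return value.replace("\\", "\\\\").replace('"', '\\"')


def graph_to_dot(graph: nx.Graph) -> str:
    """Deterministic DOT serialization with node labels and edge weights."""
    lines = ["graph metnet {"]
    for node in sorted(graph.nodes):
        attrs = graph.nodes[node]
        label = f"{node} {attrs.get('title', '')}".strip()
        extra = "".join(
            f' {key}="{_dot_escape(str(attrs[key]))}"'
            for key in sorted(attrs)
            if key not in ("title",)
        )
        lines.append(f'  "{node}" [label="{_dot_escape(label)}"{extra}];')
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
        attrs = graph.edges[u, v]
        decor = "".join(
            f' {key}="{_dot_escape(str(attrs[key]))}"' for key in sorted(attrs)
        )
        lines.append(f'  "{u}" -- "{v}" [{decor.strip()}];' if attrs else f'  "{u}" -- "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_graph(net: TwoLevelNetwork, format: str = "graphml") -> str:
    """Serialize the structural graph as GraphML or DOT.

    Nodes are present pathways labelled with number and title; edges
    carry the shared-compound count as a ``weight`` attribute. Output
    is byte-deterministic for a fixed network.
    """
    graph = to_networkx(net)
    if format == "graphml":
        return "\n".join(nx.generate_graphml(graph, named_key_ids=True)) + "\n"
    if format == "dot":
        return graph_to_dot(graph)
    raise ValueError(f"unsupported graph format: {format!r} (use 'graphml' or 'dot')")


def matrix_to_tsv(net: TwoLevelNetwork) -> str:
    """Adjacency matrix as TSV with pathway-number header row/column.

    The diagonal convention (-1 absent / 0 isolated / k neighbours) is
    preserved verbatim.
    """
    lines = ["\t" + "\t".join(net.universe)]
    for i, p in enumerate(net.universe):
        lines.append(p + "\t" + "\t".join(str(int(v)) for v in net.matrix[i]))
    return "\n".join(lines) + "\n"
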