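"""Serialization of comparison results and run configuration.

The canonical machine output of a pairwise comparison is a CSV table
(one row per pathway in the comparison domain, then a summary block
with the four global indexes); a spreadsheet (.xlsx) mirror is
optional. The topology comparison labels every node and edge of the
two structural graphs as shared or organism-specific, for coloured
graph export.

Runs are configured through a simple INI file selecting the pathway
universe, the ubiquitous-compound exclusion list, the comparison mode
and the output directory.
"""

from __future__ import annotations

import configparser
import csv
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx

from .ids import DEFAULT_UBIQUITOUS, validate_pathway_number
from .network_model import TwoLevelNetwork, graph_to_dot, to_networkx
from .similarity import ComparisonMode, PairwiseComparison

logger = logging.getLogger(__name__)

__all__ = [
    "TopologyComparison",
    "topology_comparison",
    "topology_to_graph",
    "export_topology",
    "comparison_to_csv",
    "write_comparison",
    "RunConfig",
    "load_config",
]

CSV_COLUMNS = (
    "pathway_number",
    "title",
    "sim_s",
    "sim_p",
    "sim_s_case",
    "sim_p_case",
    "reaction_union_size",
)


@dataclass(frozen=True)
class TopologyComparison:
    """Shared/unshared decomposition of two organisms' structural graphs.

    Ownership is ``both``, ``a-only`` or ``b-only``; an edge is owned
    by ``both`` only when present in both graphs, which forces both its
    endpoints to be owned by ``both``.
    """

    org_a: str
    org_b: str
    node_ownership: Mapping[str, str]
    edge_ownership: Mapping[tuple[str, str], str]


def topology_comparison(
    net_a: TwoLevelNetwork, net_b: TwoLevelNetwork
) -> TopologyComparison:
    if net_a.universe != net_b.universe:
        raise ValueError("networks were built over different pathway universes")
    nodes: dict[str, str] = {}
    for p in net_a.universe:
        in_a, in_b = net_a.is_present(p), net_b.is_present(p)
        if in_a and in_b:
            nodes[p] = "both"
        elif in_a:
            nodes[p] = "a-only"
        elif in_b:
            nodes[p] = "b-only"
    edges_a = {tuple(sorted(e)) for e in to_networkx(net_a).edges}
    edges_b = {tuple(sorted(e)) for e in to_networkx(net_b).edges}
    edges: dict[tuple[str, str], str] = {}
    for e in sorted(edges_a | edges_b):
        if e in edges_a and e in edges_b:
            edges[e] = "both"
        elif e in edges_a:
            edges[e] = "a-only"
        else:
            edges[e] = "b-only"
    return TopologyComparison(
        org_a=net_a.org_code,
        org_b=net_b.org_code,
        node_ownership=nodes,
        edge_ownership=edges,
    )


def topology_to_graph(topo: TopologyComparison) -> nx.Graph:
    graph = nx.Graph(org_a=topo.org_a, org_b=topo.org_b)
    for node in sorted(topo.node_ownership):
        graph.add_node(node, ownership=topo.node_ownership[node])
    for (u, v), ownership in sorted(topo.edge_ownership.items()):
        graph.add_edge(u, v, ownership=ownership)
    return graph


def export_topology(topo: TopologyComparison, format: str = "graphml") -> str:
    """GraphML/DOT export with an ``ownership`` attribute per element."""
    graph = topology_to_graph(topo)
    if format == "graphml":
        return "\n".join(nx.generate_graphml(graph, named_key_ids=True)) + "\n"
    if format == "dot":
        return graph_to_dot(graph)
    raise ValueError(f"unsupported graph format: {format!r} (use 'graphml' or 'dot')")


def comparison_to_csv(cmp: PairwiseComparison) -> str:
    """Canonical CSV form: per-pathway rows, then a summary block.

    Numeric cells are written at full precision (repr), never rounded;
    display rounding belongs to rendering layers. Emitting the
    per-pathway reaction-union sizes makes every global index, PsimW
    included, recomputable from the file alone.
    """
    buffer = io.StringIO()
    writer = csv.writer(buffer, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for row in cmp.rows:
        writer.writerow(
            [
                row.pathway_number,
                row.title,
                repr(row.sim_s),
                repr(row.sim_p),
                row.sim_s_case,
                row.sim_p_case,
                row.reaction_union_size,
            ]
        )
    writer.writerow([])
    writer.writerow(["summary", "org_a", cmp.org_a])
    writer.writerow(["summary", "org_b", cmp.org_b])
    writer.writerow(["summary", "mode", cmp.mode.value])
    writer.writerow(["summary", "n", cmp.n])
    for name, value in cmp.globals_dict().items():
        writer.writerow(["summary", name, repr(value)])
    return buffer.getvalue()


def write_comparison(
    cmp: PairwiseComparison, out_path: Path | str, spreadsheet: bool = False
) -> list[Path]:
    """Write a comparison as CSV (always) and .xlsx (optionally).

    ``out_path`` is the CSV path; the spreadsheet, if requested, is
    written next to it with an ``.xlsx`` suffix. Returns the paths
    written.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(comparison_to_csv(cmp))
    written = [out_path]
    if spreadsheet:
        import pandas as pd

        xlsx_path = out_path.with_suffix(".xlsx")
        frame = pd.DataFrame(
            [
                {
                    "pathway_number": r.pathway_number,
                    "title": r.title,
                    "sim_s": r.sim_s,
                    "sim_p": r.sim_p,
                    "sim_s_case": r.sim_s_case,
                    "sim_p_case": r.sim_p_case,
                    "reaction_union_size": r.reaction_union_size,
                }
                for r in cmp.rows
            ]
        )
        summary = pd.DataFrame(
            {"index": list(cmp.globals_dict()), "value": list(cmp.globals_dict().values())}
        )
        with pd.ExcelWriter(xlsx_path, engine="openpyxl") as excel:
            frame.to_excel(excel, sheet_name="pathways", index=False)
            summary.to_excel(excel, sheet_name="summary", index=False)
        written.append(xlsx_path)
    return written


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a comparison run, read from an INI file."""

    universe: tuple[str, ...]
    ubiquitous: frozenset[str] = DEFAULT_UBIQUITOUS
    mode: ComparisonMode = ComparisonMode.SET
    indexes: tuple[str, ...] = ("psim", "psim_w", "ssim", "csim")
    out_dir: Path = field(default_factory=lambda: Path("metnet-out"))


def load_config(path: Path | str) -> RunConfig:
    """Read a run configuration.

    Expected layout::

        [pathways]
        universe = 00010 00020 00030

        [compounds]
        ubiquitous = C00001 C00002 C00008 C00009

        [options]
        mode = set
        indexes = psim psim_w ssim csim
        out_dir = results
    """
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(f"config file not found: {path}")
    try:
        universe = tuple(
            validate_pathway_number(n)
            for n in parser.get("pathways", "universe").split()
        )
    except (configparser.NoSectionError, configparser.NoOptionError) as exc:
        raise ValueError(f"config missing [pathways] universe: {exc}") from exc
    if not universe:
        raise ValueError("config universe is empty")
    ubiquitous = DEFAULT_UBIQUITOUS
    if parser.has_option("compounds", "ubiquitous"):
        ubiquitous = frozenset(parser.get("compounds", "ubiquitous").split())
    mode = ComparisonMode(parser.get("options", "mode", fallback="set"))
    indexes = tuple(
        parser.get("options", "indexes", fallback="psim psim_w ssim csim").split()
    )
    out_dir = Path(parser.get("options", "out_dir", fallback="metnet-out"))
    return RunConfig(
        universe=universe,
        ubiquitous=ubiquitous,
        mode=mode,
        indexes=indexes,
        out_dir=out_dir,
    )
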