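"""Tie networks: the shared container for survey- and email-derived networks.

A :class:`TieNetwork` wraps a networkx graph together with construction
provenance (which method built it and at what threshold), because every
downstream comparison needs to know where a network came from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = ["TieNetwork", "write_network", "read_network"]


@dataclass
class TieNetwork:
    """A social network of unweighted ties with construction provenance.

    Parameters
    ----------
    graph :
        ``nx.Graph`` (undirected ties) or ``nx.DiGraph`` (directed ties).
        Self-loops are not allowed.
    method :
        Name of the construction method (``"name_generator"``,
        ``"single_recipient"``, ``"logistic"``, ``"ranked_partner"``, ...).
    threshold :
        The threshold the method was run at, if any.
    """

    graph: nx.Graph | nx.DiGraph
    method: str = "unspecified"
    threshold: float | None = None

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-ties are not allowed: {loops[:3]}")

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def n_ties(self) -> int:
        return self.graph.number_of_edges()

    def ties(self) -> frozenset:
        """Tie set: ordered tuples if directed, sorted tuples otherwise."""
        if self.directed:
            return frozenset((u, v) for u, v in self.graph.edges)
        return frozenset(tuple(sorted((u, v))) for u, v in self.graph.edges)

    def undirected_graph(self) -> nx.Graph:
        """Union-symmetrized undirected view (identity for undirected nets)."""
        if not self.directed:
            return self.graph
        return self.graph.to_undirected(reciprocal=False)

    def density_undirected(self) -> float:
        """Tie density of the union-symmetrized network (ties / unordered pairs)."""
        return nx.density(self.undirected_graph())

    def provenance(self) -> dict:
        return {
            "method": self.method,
            "threshold": self.threshold,
            "directed": self.directed,
            "n_nodes": self.graph.number_of_nodes(),
            "n_ties": self.n_ties,
        }


def write_network(net: TieNetwork, basepath: str | Path) -> dict[str, Path]:
    """Serialize a network as edge-list CSV + GraphML + a JSON provenance sidecar.

    ``basepath`` is used as a stem; three files are written next to it.
    """
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    edges_path = base.with_suffix(".edges.csv")
    graphml_path = base.with_suffix(".graphml")
    sidecar_path = base.with_suffix(".json")

    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write(f"# directed={net.directed}\n")
        fh.write("src,dst\n")
        for u, v in sorted(net.ties()):
            fh.write(f"{u},{v}\n")
    nx.write_graphml(net.graph, graphml_path)
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        json.dump(net.provenance(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"edges": edges_path, "graphml": graphml_path, "sidecar": sidecar_path}


def read_network(basepath: str | Path) -> TieNetwork:
    """Load a network written by :func:`write_network` (edge list + sidecar)."""
    base = Path(basepath)
    with open(base.with_suffix(".json"), encoding="utf-8") as fh:
        meta = json.load(fh)
    graph = nx.DiGraph() if meta["directed"] else nx.Graph()
    with open(base.with_suffix(".edges.csv"), encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line == "src,dst":
                continue
            u, v = line.split(",")
            graph.add_edge(u, v)
    return TieNetwork(graph, method=meta["method"], threshold=meta["threshold"])
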