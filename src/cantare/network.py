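"""Analyte network construction and neighborhood extraction.

The top table is summarized as an undirected graph: one node per distinct
analyte, one edge per selected pairwise fit (the edge keeps the fit's
statistics as attributes). Neighborhoods of order k — all nodes within
graph distance k of a seed — provide the candidate predictor sets for the
downstream logistic models. Edges are undirected for neighborhood purposes
even though each underlying regression had a response/predictor
orientation; the orientation is retained as edge metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from cantare.pairwise import PairwiseFit, TopTable

logger = logging.getLogger(__name__)


class AnalyteNetwork:
    """Undirected analyte graph whose edges carry pairwise-fit statistics."""

    def __init__(self, graph: nx.Graph | None = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_ome(self, ome: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("ome") == ome
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnalyteNetwork):
            return NotImplemented
        return (
            set(self.graph.nodes) == set(other.graph.nodes)
            and set(map(frozenset, self.graph.edges))
            == set(map(frozenset, other.graph.edges))
        )


@dataclass
class Neighborhood:
    """All nodes within graph distance ``order`` of ``seed`` (inclusive)."""

    seed: str
    order: int
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def _ome_of(name: str, fit: PairwiseFit, role: str) -> str:
    explicit = fit.response_ome if role == "response" else fit.predictor_ome
    if explicit:
        return explicit
    return name.split("_", 1)[0] if "_" in name else ""


def build_network(top_table: TopTable) -> AnalyteNetwork:
    """One node per distinct analyte, one edge per top-table entry.

    If two entries link the same unordered analyte pair (both regression
    directions survived), the smaller-p entry keeps the edge and the other
    is logged and dropped.
    """
    net = AnalyteNetwork()
    g = net.graph
    duplicates = 0
    for fit in top_table.entries:
        for name, role in ((fit.response, "response"), (fit.predictor, "predictor")):
            if name not in g:
                g.add_node(name, ome=_ome_of(name, fit, role), label=name)
        u, v = fit.response, fit.predictor
        if g.has_edge(u, v):
            duplicates += 1
            if fit.p_target >= g.edges[u, v]["p_target"]:
                logger.info(
                    "duplicate pair %s--%s: keeping p=%.3g, dropping p=%.3g",
                    u, v, g.edges[u, v]["p_target"], fit.p_target,
                )
                continue
            logger.info(
                "duplicate pair %s--%s: replacing p=%.3g with p=%.3g",
                u, v, g.edges[u, v]["p_target"], fit.p_target,
            )
        g.add_edge(
            u,
            v,
            mode=fit.mode,
            beta0=fit.beta0,
            beta1=fit.beta1,
            beta2=fit.beta2,
            beta3=fit.beta3,
            p_target=fit.p_target,
            max_abs_dffits=fit.max_abs_dffits,
            n=fit.n,
            response=fit.response,
            predictor=fit.predictor,
        )
    net.duplicates_dropped = duplicates  # type: ignore[attr-defined]
    return net


def neighborhood(network: AnalyteNetwork, seed: str, order: int) -> Neighborhood:
    """Breadth-first closure of ``seed`` to depth ``order`` (seed included)."""
    if seed not in network.graph:
        raise KeyError(f"unknown seed node {seed!r}")
    if order < 1:
        raise ValueError("order must be >= 1")
    members = nx.single_source_shortest_path_length(network.graph, seed, cutoff=order)
    return Neighborhood(seed=seed, order=order, members=frozenset(members))


def enumerate_seed_neighborhoods(
    network: AnalyteNetwork,
    seed_ome: str = "mb",
    order: int = 2,
    min_nodes: int = 4,
) -> list[Neighborhood]:
    """Order-k neighborhood of every seed-ome node with >= min_nodes members.

    The member count includes the seed itself. Results are returned in
    ascending seed-name order for determinism.
    """
    out = []
    for seed in network.nodes_of_ome(seed_ome):
        hood = neighborhood(network, seed, order)
        if len(hood) >= min_nodes:
            out.append(hood)
    return out
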