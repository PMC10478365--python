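"""Graph construction and topology statistics for the comorbidity networks.

The *complete* network of a disease pair is the subgraph of the global
associative network induced on the entities associated with both diseases;
the *regulatory* network further restricts the edges to regulation types.
Centralities (degree, betweenness, and the neighbour-pair clustering form
written ``CC = 2 e_n / (k_n (k_n - 1))``) are computed on the entity-level
simple undirected graph and are all normalized to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .io_model import (
    REGULATORY_TYPES,
    AssociativeNetwork,
    DiseaseAssociationTable,
    InteractionType,
    ValidationError,
)

logger = logging.getLogger("comorbid_rank")

__all__ = [
    "NetworkSummary",
    "CentralityRecord",
    "HubCriteria",
    "CtsInput",
    "intersect_disease_networks",
    "extract_regulatory_subnetwork",
    "summarize_network",
    "compute_centralities",
    "cross_talk_specificity",
    "detect_hubs",
    "write_network_summary",
    "write_centralities",
]


@dataclass(frozen=True)
class NetworkSummary:
    """Node and per-interaction-type edge accounting for one network."""

    n_gene_nodes: int
    n_protein_nodes: int
    per_type_edge_counts: Mapping[InteractionType, int]
    total_edges: int

    @property
    def n_nodes(self) -> int:
        return self.n_gene_nodes + self.n_protein_nodes


@dataclass(frozen=True)
class CentralityRecord:
    """Normalized centralities of one gene entity.

    dc = degree / (N - 1); bc = betweenness normalized by (N-1)(N-2)/2;
    cc = 2 e_n / (k_n (k_n - 1)), zero when the degree is below 2.
    """

    entity: str
    dc: float
    bc: float
    cc: float
    degree_raw: int


@dataclass(frozen=True)
class HubCriteria:
    """Hub cutoffs: bc and cc are inclusive (>=), degree is strict (>)."""

    bc_min: float = 0.005
    cc_min: float = 0.2
    degree_gt: int = 40

    def __post_init__(self) -> None:
        if self.bc_min < 0 or self.cc_min < 0 or self.degree_gt < 0:
            raise ValidationError("hub cutoffs must be nonnegative")


@dataclass(frozen=True)
class CtsInput:
    """Link counts for cross-talk specificity: k_i in the analyzed network,
    m_i in the global network."""

    k_i: int
    m_i: int


def intersect_disease_networks(
    assoc: DiseaseAssociationTable,
    disease_a: str,
    disease_b: str,
    global_net: AssociativeNetwork,
) -> AssociativeNetwork:
    """Complete comorbidity network: subgraph of `global_net` induced on the
    entities associated with BOTH diseases (union over association sources)."""
    genes_a = assoc.genes_for(disease_a)
    genes_b = assoc.genes_for(disease_b)
    shared = genes_a & genes_b
    name = f"complete_{disease_a}_{disease_b}"
    if not shared:
        logger.warning(
            "diseases %r and %r share no associated genes; complete network empty",
            disease_a, disease_b,
        )
        return AssociativeNetwork(name=name)
    net = global_net.induced_on(shared, name=name)
    if not net.nodes:
        logger.warning(
            "none of the %d shared genes of %r/%r appear in the global network",
            len(shared), disease_a, disease_b,
        )
    return net


def extract_regulatory_subnetwork(
    net: AssociativeNetwork,
    regulatory_types: Iterable[InteractionType] | None = None,
) -> AssociativeNetwork:
    """Keep only regulatory edges (default: everything except associative and
    protein-protein); isolated nodes are dropped."""
    types = frozenset(regulatory_types) if regulatory_types is not None else REGULATORY_TYPES
    sub = AssociativeNetwork(name=f"{net.name}_regulatory" if net.name else "regulatory")
    sub.edges = {e for e in net.edges if e.itype in types}
    for e in sub.edges:
        sub.nodes.add(e.source)
        sub.nodes.add(e.target)
    return sub


def summarize_network(net: AssociativeNetwork) -> NetworkSummary:
    counts = {t: 0 for t in InteractionType}
    for e in net.edges:
        counts[e.itype] += 1
    return NetworkSummary(
        n_gene_nodes=net.n_gene_nodes,
        n_protein_nodes=net.n_protein_nodes,
        per_type_edge_counts=counts,
        total_edges=len(net.edges),
    )


def compute_centralities(net: AssociativeNetwork) -> list[CentralityRecord]:
    """Per-entity normalized degree, betweenness and clustering centralities.

    The network is collapsed to a simple undirected graph over gene entities
    (edge types and gene/protein classes merged, multi-edges counted once).
    Shortest paths over disconnected pairs contribute 0 to betweenness.
    """
    g = net.entity_graph()
    n = g.number_of_nodes()
    if n < 2:
        raise ValidationError(f"centralities undefined for networks with {n} node(s)")
    display = net.entity_display()
    dc = nx.degree_centrality(g)
    bc = nx.betweenness_centrality(g, normalized=True)
    cc = nx.clustering(g)
    records = [
        CentralityRecord(
            entity=display[v],
            dc=float(dc[v]),
            bc=float(bc[v]),
            cc=float(cc[v]),
            degree_raw=int(g.degree[v]),
        )
        for v in g.nodes
    ]
    records.sort(key=lambda r: r.entity.upper())
    return records


def cross_talk_specificity(inp: CtsInput) -> float:
    """CTS = K_i / M_i: the fraction of a gene's global links that lie inside
    the analyzed network."""
    if inp.m_i == 0:
        raise ValidationError("CTS undefined: gene has no links in the global network")
    if inp.k_i < 0 or inp.k_i > inp.m_i:
        raise ValidationError(
            f"inconsistent CTS input: k_i={inp.k_i} must satisfy 0 <= k_i <= m_i={inp.m_i}"
        )
    return inp.k_i / inp.m_i


def detect_hubs(
    records: Iterable[CentralityRecord], criteria: HubCriteria = HubCriteria()
) -> set[str]:
    """Entities passing all three hub cutoffs (bc >=, cc >=, degree >)."""
    return {
        r.entity
        for r in records
        if r.bc >= criteria.bc_min
        and r.cc >= criteria.cc_min
        and r.degree_raw > criteria.degree_gt
    }


def write_network_summary(summary: NetworkSummary, path: str | Path) -> None:
    """TSV (type, count) with gene/protein node rows and a TOTAL edge row."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("category\tcount\n")
        fh.write(f"gene_nodes\t{summary.n_gene_nodes}\n")
        fh.write(f"protein_nodes\t{summary.n_protein_nodes}\n")
        for t in InteractionType:
            fh.write(f"{t.value}\t{summary.per_type_edge_counts.get(t, 0)}\n")
        fh.write(f"TOTAL\t{summary.total_edges}\n")


def write_centralities(records: Iterable[CentralityRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity\tdc\tbc\tcc\tdegree_raw\n")
        for r in records:
            fh.write(f"{r.entity}\t{r.dc:.10g}\t{r.bc:.10g}\t{r.cc:.10g}\t{r.degree_raw}\n")
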