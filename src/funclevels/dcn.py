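"""Domain co-occurrence networks and aggregated neighbor-counting.

A species' DCN has one node per Pfam-style domain family observed in
the proteome and an unweighted edge between any two families found
together in at least one protein (the observed co-occurrence count is
kept as edge metadata but never scored).

The level-3 predictor places a target's detected domain families as
*centers* on the DCN of the species most similar to the target and
transfers GO terms from the centers' radius-1 neighbors; if those carry
no annotation at all it falls back to the radius-2 ring. Each distinct
GO term g is scored

    S_dcn(g) = 0.3 * f(g),
    f(g) = (# neighbor domains annotated with g)
           / (total GO-term occurrences over all neighbor domains)

so the f values sum to 1 and the confidences to 0.3. The counting unit
is the neighbor domain: duplicate annotation rows for one domain count
once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx

from .core import AnnotationMap, HomologyHit, Prediction

__all__ = [
    "DomainAssignmentTable",
    "DomainNetwork",
    "build_dcn",
    "select_species",
    "neighbor_set",
    "neighbor_counting_predict",
    "read_assignments_tsv",
    "write_assignments_tsv",
]

logger = logging.getLogger(__name__)

DCN_SCALE = 0.3  # upper end of the level-3 confidence interval


@dataclass
class DomainAssignmentTable:
    """Per-species protein → ordered domain-family list.

    A protein may carry the same family more than once (tandem repeats)
    and may carry none.
    """

    species: str
    assignments: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class DomainNetwork:
    """Undirected co-occurrence graph of domain families for one species."""

    species: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def write_edgelist_tsv(self, stream: IO[str]) -> None:
        for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
            count = self.graph.edges[u, v].get("count", 1)
            stream.write(f"{u}\t{v}\t{count}\n")

    def write_graphml(self, path: str) -> None:
        nx.write_graphml(self.graph, path)


def read_assignments_tsv(
    stream: IO[str] | Iterable[str],
) -> dict[str, DomainAssignmentTable]:
    """Read 3-column TSV (species, protein, comma-separated domain list)."""
    tables: dict[str, DomainAssignmentTable] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected >= 2 columns")
        species, protein = fields[0], fields[1]
        domains = [d for d in fields[2].split(",") if d] if len(fields) > 2 else []
        tables.setdefault(species, DomainAssignmentTable(species))
        tables[species].assignments[protein] = domains
    return tables


def write_assignments_tsv(
    tables: Mapping[str, DomainAssignmentTable], stream: IO[str]
) -> None:
    for species in sorted(tables):
        table = tables[species]
        for protein in sorted(table.assignments):
            domains = ",".join(table.assignments[protein])
            stream.write(f"{species}\t{protein}\t{domains}\n")


def build_dcn(assignments: DomainAssignmentTable) -> DomainNetwork:
    """Build the co-occurrence network of one species' proteome.

    Every distinct family in any protein becomes a node; two distinct
    families co-occurring within one protein get one edge. Repeats of a
    family within a protein never create a self-loop. Deterministic in
    protein order and under duplicated proteins.
    """
    g = nx.Graph()
    for protein in sorted(assignments.assignments):
        domains = assignments.assignments[protein]
        distinct = sorted(set(domains))
        g.add_nodes_from(distinct)
        for i, a in enumerate(distinct):
            for b in distinct[i + 1 :]:
                if g.has_edge(a, b):
                    g.edges[a, b]["count"] += 1
                else:
                    g.add_edge(a, b, count=1)
    return DomainNetwork(species=assignments.species, graph=g)


def select_species(hits: Iterable[HomologyHit]) -> str:
    """Most closely related species: the species tag of the best PSI-BLAST hit.

    Best = minimum e-value; ties broken by lexicographically smallest
    species id. Raises ``ValueError`` when no species-tagged hit exists,
    signalling that no DCN is applicable to the target.
    """
    tagged = [h for h in hits if h.source == "psiblast" and h.species is not None]
    if not tagged:
        raise ValueError("no species-tagged PSI-BLAST hits: cannot pick a DCN")
    return min(tagged, key=lambda h: (h.evalue, h.species)).species


def neighbor_set(
    network: DomainNetwork, centers: set[str], radius: int
) -> set[str]:
    """Domain families within ``radius`` hops of any center, centers excluded.

    ``radius`` is 1 (direct neighbors) or 2 (shortest-path distance at
    most 2). Callers must intersect detected domains with the network's
    nodes first; an unknown center raises.
    """
    if radius not in (1, 2):
        raise ValueError(f"radius must be 1 or 2, got {radius}")
    missing = centers - network.nodes
    if missing:
        raise KeyError(f"centers not in network: {sorted(missing)}")
    out: set[str] = set()
    for c in centers:
        out.update(
            nx.single_source_shortest_path_length(network.graph, c, cutoff=radius)
        )
    return out - centers


def neighbor_counting_predict(
    network: DomainNetwork,
    centers: set[str],
    domain_annotations: AnnotationMap,
    *,
    target: str = "",
    radius2_fallback: bool = True,
) -> list[Prediction]:
    """Aggregated neighbor-counting on a DCN.

    GO terms are collected from the centers' radius-1 neighbors; when
    that yields nothing and ``radius2_fallback`` is set, the ring of
    domains at distance exactly 2 is used instead. Confidences are
    ``0.3 * f(g)`` with the occurrence frequencies f summing to 1.
    Returns an empty list when neither radius yields an annotated
    neighbor.
    """
    ring1 = neighbor_set(network, centers, radius=1)
    preds = _count_ring(ring1, domain_annotations, target)
    if not preds and radius2_fallback:
        ring2 = neighbor_set(network, centers, radius=2) - ring1
        preds = _count_ring(ring2, domain_annotations, target)
    return preds


def _count_ring(
    ring: set[str], domain_annotations: AnnotationMap, target: str
) -> list[Prediction]:
    counts: dict[str, int] = {}
    total = 0
    for d in sorted(ring):
        terms = domain_annotations.get(d, set())
        for g in terms:
            counts[g] = counts.get(g, 0) + 1
        total += len(terms)
    if total == 0:
        return []
    return [
        Prediction(target=target, go_term=g,
                   confidence=DCN_SCALE * n / total, level=3)
        for g, n in sorted(counts.items())
    ]
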