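"""Gene Ontology DAG: loading, ancestor propagation, depth, similarity.

The ontology is held as a parent-pointer map restricted to a configured
relation set (``is_a`` by default, optionally ``part_of``). The three GO
namespaces are kept strictly separate: propagation stops at the
namespace root and there is no artificial super-root, so terms from
different namespaces never share ancestors.

Two notions defined here are used throughout the evaluation stack:

* **propagation** (the true-path rule): a set of terms is expanded with
  every ancestor up to the namespace root;
* **path-overlap similarity**: for terms g1, g2 with root-path closures
  r1, r2 (each the union of all paths from the term to the root,
  including the term itself),

      Sim(g1, g2) = |r1 ∩ r2| / max(|r1|, |r2|),

  which is 1 exactly when the closures coincide and always positive
  within one namespace because the root is shared.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Literal

import networkx as nx
import obonet

__all__ = [
    "GoDag",
    "load_obo",
    "propagate",
    "term_depth",
    "semantic_similarity",
    "write_ancestors_tsv",
]

DepthConvention = Literal["shortest", "longest"]


class OboParseError(ValueError):
    """Raised when an OBO stream cannot be parsed or validated."""


@dataclass
class GoDag:
    """An acyclic is_a/part_of hierarchy of GO terms.

    ``parents`` maps each term to its direct parents under the active
    relation set; ``roots`` maps each namespace to its parentless terms
    (a single root for real GO, possibly several for sliced ontologies).
    ``alt_ids`` maps secondary ids onto primary ones.
    """

    parents: dict[str, frozenset[str]]
    namespace: dict[str, str]
    alt_ids: dict[str, str] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)
    relations: tuple[str, ...] = ("is_a",)

    def __post_init__(self) -> None:
        self._children: dict[str, set[str]] = {t: set() for t in self.parents}
        for term, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise ValueError(f"parent {p} of {term} is not a term")
                self._children[p].add(term)
        self._validate_acyclic()
        self.roots: dict[str, frozenset[str]] = {}
        for term, ps in self.parents.items():
            if not ps:
                ns = self.namespace[term]
                self.roots[ns] = self.roots.get(ns, frozenset()) | {term}
        # caches keyed by term id; cleared nowhere because the dag is frozen in use
        self._ancestors_cache: dict[str, frozenset[str]] = {}
        self._depth_cache: dict[tuple[str, str], int] = {}

    # -- queries ---------------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents or term in self.alt_ids

    def __len__(self) -> int:
        return len(self.parents)

    def resolve(self, term: str) -> str:
        """Map an alt_id onto its primary id; identity for primary ids."""
        if term in self.parents:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise KeyError(f"unknown GO term {term!r}")

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including ``term`` itself."""
        term = self.resolve(term)
        cached = self._ancestors_cache.get(term)
        if cached is not None:
            return cached
        out = {term}
        frontier = [term]
        while frontier:
            t = frontier.pop()
            for p in self.parents[t]:
                if p not in out:
                    out.add(p)
                    frontier.append(p)
        result = frozenset(out)
        self._ancestors_cache[term] = result
        return result

    def children(self, term: str) -> frozenset[str]:
        return frozenset(self._children[self.resolve(term)])

    # -- internals -------------------------------------------------------

    def _validate_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        g.add_edges_from(
            (t, p) for t, ps in self.parents.items() for p in ps
        )
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OboParseError(f"ontology contains a cycle: {cycle}")


def load_obo(
    stream: IO[str] | str,
    relations: Iterable[str] = ("is_a",),
) -> GoDag:
    """Load an OBO 1.2/1.4 flat file into a :class:`GoDag`.

    Obsolete terms are dropped, ``alt_id`` entries are recorded as
    aliases of their primary term, and edges are restricted to
    ``relations`` (``is_a`` by default; add ``part_of`` to follow
    part-of paths as well). Edges pointing at terms outside the file
    (dangling references in ontology slices) are dropped.
    """
    relations = tuple(relations)
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            graph = obonet.read_obo(stream, ignore_obsolete=True)
        except Exception as exc:  # obonet raises plain ValueError
            raise OboParseError(f"malformed OBO stream: {exc}") from exc

    parents: dict[str, frozenset[str]] = {}
    namespace: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    names: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        ns = data.get("namespace", "biological_process")
        namespace[term] = ns
        names[term] = data.get("name", term)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
        ps = set()
        if "is_a" in relations:
            ps.update(p for p in data.get("is_a", []) if p in graph)
        for rel_line in data.get("relationship", []):
            rel, _, target = rel_line.partition(" ")
            target = target.split("!")[0].strip()
            if rel in relations and rel != "is_a" and target in graph:
                ps.add(target)
        parents[term] = frozenset(ps)
    if not parents:
        raise OboParseError("OBO stream contains no usable [Term] stanzas")
    return GoDag(parents, namespace, alt_ids, names, relations)


def propagate(
    dag: GoDag,
    terms: Iterable[str],
    on_unknown: Literal["error", "skip"] = "error",
) -> set[str]:
    """Expand ``terms`` with all ancestors up to each namespace root.

    The result is a superset of the (resolved) input and the operation is
    idempotent. Unknown terms raise by default; with
    ``on_unknown="skip"`` they are dropped with a warning.
    """
    out: set[str] = set()
    for t in terms:
        try:
            out |= dag.ancestors(t)
        except KeyError:
            if on_unknown == "skip":
                warnings.warn(f"skipping unknown GO term {t!r}", stacklevel=2)
            else:
                raise
    return out


def term_depth(
    dag: GoDag,
    term: str,
    convention: DepthConvention = "shortest",
) -> int:
    """Number of nodes on a path from ``term`` to its namespace root.

    Both endpoints count, so the root has depth 1 and a direct child of
    the root has depth 2. On multi-path DAGs the ``shortest`` convention
    (default) takes the minimum node count over all root paths;
    ``longest`` takes the maximum.
    """
    term = dag.resolve(term)
    key = (term, convention)
    cached = dag._depth_cache.get(key)
    if cached is not None:
        return cached
    pick = min if convention == "shortest" else max
    # iterative DFS with memoisation (recursion would overflow on deep chains)
    stack = [term]
    while stack:
        t = stack[-1]
        if (t, convention) in dag._depth_cache:
            stack.pop()
            continue
        ps = dag.parents[t]
        if not ps:
            dag._depth_cache[(t, convention)] = 1
            stack.pop()
            continue
        missing = [p for p in ps if (p, convention) not in dag._depth_cache]
        if missing:
            stack.extend(missing)
        else:
            dag._depth_cache[(t, convention)] = 1 + pick(
                dag._depth_cache[(p, convention)] for p in ps
            )
            stack.pop()
    return dag._depth_cache[key]


def semantic_similarity(dag: GoDag, g1: str, g2: str) -> float:
    """Path-overlap similarity of two GO terms, in [0, 1].

    Each term's root path is realised as its full ancestor closure
    (the term plus every ancestor); the score is the closure overlap
    divided by the larger closure size. Terms from different namespaces
    share no ancestors and score 0 (with a warning).
    """
    g1, g2 = dag.resolve(g1), dag.resolve(g2)
    if dag.namespace[g1] != dag.namespace[g2]:
        warnings.warn(
            f"cross-namespace similarity {g1}/{g2} defined as 0", stacklevel=2
        )
        return 0.0
    r1, r2 = dag.ancestors(g1), dag.ancestors(g2)
    return len(r1 & r2) / max(len(r1), len(r2))


def write_ancestors_tsv(dag: GoDag, terms: Iterable[str], stream: IO[str]) -> None:
    """Export ancestor closures as 2-column TSV (term, ancestor)."""
    for t in sorted({dag.resolve(t) for t in terms}):
        for anc in sorted(dag.ancestors(t)):
            stream.write(f"{t}\t{anc}\n")
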