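"""LCA-indexed GO-term pair features (the F2 block).

The Gene Ontology subontologies (BP, CC, MF) are rooted DAGs of terms with
child->parent ``is_a``/``part_of`` links.  For every training protein pair
we find the lowest common ancestor (LCA) of the union of the two proteins'
annotated terms.  The distinct LCAs, processed from the deepest hierarchical
level upward, partition the DAG into mutually exclusive clusters: each LCA
is grouped with all of its descendants not already claimed by an earlier
(deeper) cluster.  A pair is then encoded as one integer per cluster: the
number of distinct terms of that cluster lying on any ascending path, within
the cluster, from one of the pair's annotated terms up to the cluster's LCA
root (endpoints included).  Because the partition is rebuilt from whatever
training pairs are supplied, both the number and the values of these
features adapt to the training data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger("stackppi")

ONTOLOGIES = ("BP", "CC", "MF")


class GoDag:
    """One rooted GO subontology as a DAG of child->parent edges."""

    def __init__(self, ontology: str, edges: Iterable[tuple[str, str]]):
        graph = nx.DiGraph()
        graph.add_edges_from(edges)  # direction: child -> parent
        if graph.number_of_nodes() == 0:
            raise ValueError("empty ontology graph")
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"ontology graph has a cycle through {cycle[0][0]!r}")
        roots = [t for t in graph.nodes if graph.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValueError(
                f"expected exactly one root, found {len(roots)}: {sorted(roots)[:5]}"
            )
        self.ontology = ontology
        self.graph = graph
        self.root: str = roots[0]
        self._levels: dict[str, int] | None = None
        # per-instance memoized traversals (DAGs are immutable once built)
        self._ancestors = lru_cache(maxsize=None)(self._ancestors_uncached)
        self._descendants = lru_cache(maxsize=None)(self._descendants_uncached)

    def __getstate__(self):
        state = self.__dict__.copy()
        del state["_ancestors"], state["_descendants"]  # unpicklable caches
        return state

    def __setstate__(self, state):
        self.__dict__.update(state)
        self._ancestors = lru_cache(maxsize=None)(self._ancestors_uncached)
        self._descendants = lru_cache(maxsize=None)(self._descendants_uncached)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def _require(self, term: str) -> None:
        if term not in self.graph:
            raise KeyError(f"term {term!r} not in {self.ontology} ontology")

    def parents(self, term: str) -> set[str]:
        self._require(term)
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        self._require(term)
        return set(self.graph.predecessors(term))

    def _ancestors_uncached(self, term: str) -> frozenset[str]:
        self._require(term)
        return frozenset(nx.descendants(self.graph, term) | {term})

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestors of ``term``, inclusive of the term itself."""
        return self._ancestors(term)

    def _descendants_uncached(self, term: str) -> frozenset[str]:
        self._require(term)
        return frozenset(nx.ancestors(self.graph, term) | {term})

    def descendants(self, term: str) -> frozenset[str]:
        """Descendants of ``term``, inclusive of the term itself."""
        return self._descendants(term)

    def level(self, term: str) -> int:
        """Hierarchical level: length of the longest path from the root."""
        if self._levels is None:
            levels: dict[str, int] = {}
            # child->parent edges: walk terms parents-first
            for t in reversed(list(nx.topological_sort(self.graph))):
                ps = list(self.graph.successors(t))
                levels[t] = 0 if not ps else 1 + max(levels[p] for p in ps)
            self._levels = levels
        self._require(term)
        return self._levels[term]


@dataclass(frozen=True)
class LcaPartition:
    """The ordered LCA list and the clusters they root.

    ``sorted_lcas`` is ordered deepest hierarchical level first (the order
    in which clusters were carved out); ``clusters[i]`` is the term set of
    the cluster rooted at ``sorted_lcas[i]``; ``cluster_of`` maps each
    clustered term to its cluster index.  Terms outside every cluster are
    legal and contribute nothing to encodings.
    """

    ontology: str
    sorted_lcas: tuple[str, ...]
    clusters: tuple[frozenset[str], ...]
    cluster_of: Mapping[str, int] = field(repr=False)

    @property
    def n_features(self) -> int:
        return len(self.sorted_lcas)


def pair_lca(dag: GoDag, terms_i: set[str], terms_j: set[str]) -> str | None:
    """The designated lowest common ancestor of a protein pair.

    The LCA is taken over the union of both proteins' term sets: the common
    ancestor (every term counted as an ancestor of itself) of every term in
    the union with the greatest hierarchical level.  Among equally deep
    candidates the lexicographically smallest id is chosen.  Returns None
    when either set is empty.
    """
    if not terms_i or not terms_j:
        return None
    union = set(terms_i) | set(terms_j)
    common: set[str] | None = None
    for term in union:
        anc = dag.ancestors(term)
        common = set(anc) if common is None else common & anc
    assert common  # the root is an ancestor of everything
    best_level = max(dag.level(t) for t in common)
    return min(t for t in common if dag.level(t) == best_level)


def partition_dag(
    dag: GoDag,
    training_pairs: Sequence[tuple[set[str], set[str]]],
) -> LcaPartition:
    """Partition the DAG by the LCAs of the training pairs.

    Duplicate LCAs are collapsed; LCAs are processed deepest level first
    (ties broken lexicographically); each cluster is the LCA plus all of its
    descendants not already assigned to an earlier cluster.
    """
    if not training_pairs:
        raise ValueError("cannot partition with an empty training set")
    lcas: set[str] = set()
    n_skipped = 0
    for terms_i, terms_j in training_pairs:
        lca = pair_lca(dag, terms_i, terms_j)
        if lca is None:
            n_skipped += 1
        else:
            lcas.add(lca)
    if n_skipped:
        logger.info(
            "%d/%d pairs had no %s annotations and contributed no LCA",
            n_skipped, len(training_pairs), dag.ontology,
        )
    if not lcas:
        raise ValueError("no pair produced a computable LCA")
    ordered = sorted(lcas, key=lambda t: (-dag.level(t), t))
    clusters: list[frozenset[str]] = []
    cluster_of: dict[str, int] = {}
    assigned: set[str] = set()
    for idx, lca in enumerate(ordered):
        members = frozenset(dag.descendants(lca) - assigned)
        clusters.append(members)
        for t in members:
            cluster_of[t] = idx
        assigned |= members
    return LcaPartition(
        ontology=dag.ontology,
        sorted_lcas=tuple(ordered),
        clusters=tuple(clusters),
        cluster_of=cluster_of,
    )


def _counted_terms(
    dag: GoDag, cluster: frozenset[str], lca: str, start: str
) -> set[str]:
    """Distinct cluster terms on ascending paths start -> lca inside the cluster."""
    # terms reachable upward from `start` without leaving the cluster
    up: set[str] = set()
    frontier = [start]
    while frontier:
        t = frontier.pop()
        if t in up:
            continue
        up.add(t)
        frontier.extend(p for p in dag.parents(t) if p in cluster)
    if lca not in up:
        return set()
    # keep only terms from which the LCA root is still reachable in-cluster
    on_path: set[str] = set()
    frontier = [lca]
    while frontier:
        t = frontier.pop()
        if t in on_path:
            continue
        on_path.add(t)
        frontier.extend(c for c in dag.children(t) if c in up and c not in on_path)
    return on_path & up


def encode_pair(
    partition: LcaPartition,
    dag: GoDag,
    terms_i: set[str],
    terms_j: set[str],
) -> np.ndarray:
    """Encode a pair as per-cluster ascending-path node counts.

    For each cluster the value is the number of distinct cluster terms lying
    on any ascending path (restricted to the cluster) from one of the pair's
    annotated terms up to the cluster's LCA root, both endpoints included.
    Annotated terms outside every cluster, and unannotated pairs, contribute
    zero.
    """
    counts = np.zeros(partition.n_features, dtype=int)
    union = (set(terms_i) | set(terms_j)) & set(partition.cluster_of)
    per_cluster: dict[int, set[str]] = {}
    for term in union:
        per_cluster.setdefault(partition.cluster_of[term], set()).add(term)
    for idx, terms in per_cluster.items():
        lca = partition.sorted_lcas[idx]
        cluster = partition.clusters[idx]
        visited: set[str] = set()
        for term in terms:
            visited |= _counted_terms(dag, cluster, lca, term)
        counts[idx] = len(visited)
    return counts
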