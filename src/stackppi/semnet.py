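"""Resnik-similarity PPI network and topology pair features (the F3 block).

A reference network N_S links the proteins confirmed as interacting in the
training labels.  Independently, every training protein pair is scored by
Resnik semantic similarity: the information content (IC) of the most
informative common ancestor, maximized over the cross product of the two
proteins' annotation sets (and, by default, over the three subontologies).
IC(t) = -ln p(t), with p(t) the fraction of corpus proteins annotated to t
or any of its descendants (ancestor propagation).  A similarity threshold
theta_R is chosen from the observed values so that the thresholded network
N_PPI matches the average degree of N_S as closely as possible; ties prefer
the larger threshold (sparser network).  Five link-prediction features are
then read off N_PPI for any pair: common neighbors, Jaccard, Adamic-Adar,
preferential attachment and the Otsuka-Ochiai (cosine) coefficient.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .go_features import GoDag

logger = logging.getLogger("stackppi")

TOPOLOGY_FEATURE_NAMES = (
    "common_neighbors",
    "jaccard",
    "adamic_adar",
    "preferential_attachment",
    "otsuka_ochiai",
)


class IcTable:
    """Per-term information content from an annotation corpus.

    Counts propagate upward: an annotation of term t counts toward t and
    every ancestor of t, so p(root) = 1 and IC(root) = 0.  Terms never seen
    in the corpus (count zero) have undefined -ln 0; they are assigned the
    corpus maximum IC plus one natural-log unit, so unseen terms rank as
    maximally informative without producing infinities.
    """

    def __init__(self, dag: GoDag, annotations: Mapping[str, Iterable[str]]):
        counts: dict[str, int] = {}
        n_proteins = 0
        for _, terms in sorted(annotations.items()):
            closure: set[str] = set()
            for t in terms:
                if t in dag:
                    closure |= dag.ancestors(t)
            if not closure:
                continue
            n_proteins += 1
            for t in closure:
                counts[t] = counts.get(t, 0) + 1
        self.dag = dag
        self.n_proteins = n_proteins
        self._ic: dict[str, float] = {}
        if n_proteins:
            for t, c in counts.items():
                self._ic[t] = -math.log(c / n_proteins)
        self._unseen_ic = (max(self._ic.values()) + 1.0) if self._ic else 0.0

    def ic(self, term: str) -> float:
        if term not in self.dag:
            raise KeyError(f"term {term!r} not in {self.dag.ontology} ontology")
        return self._ic.get(term, self._unseen_ic)

    @property
    def max_ic(self) -> float:
        return max(self._ic.values(), default=0.0)


def resnik_term_sim(ic: IcTable, dag: GoDag, t_i: str, t_j: str) -> float:
    """IC of the most informative common ancestor of two terms."""
    common = dag.ancestors(t_i) & dag.ancestors(t_j)
    return max(ic.ic(t) for t in common)


def resnik_protein_sim(
    ic: IcTable, dag: GoDag, terms_i: set[str], terms_j: set[str]
) -> float:
    """Maximum term-level Resnik similarity over the annotation cross product.

    Proteins with an empty annotation set on either side score 0.
    """
    terms_i = {t for t in terms_i if t in dag}
    terms_j = {t for t in terms_j if t in dag}
    if not terms_i or not terms_j:
        return 0.0
    return max(resnik_term_sim(ic, dag, a, b) for a in terms_i for b in terms_j)


def build_reference_network(
    proteins: Iterable[str], positive_pairs: Iterable[tuple[str, str]]
) -> nx.Graph:
    """N_S: proteins linked only when labeled interacting in training."""
    net = nx.Graph()
    net.add_nodes_from(proteins)
    for a, b in positive_pairs:
        if a != b:
            net.add_edge(a, b)
    return net


def build_similarity_network(
    proteins: Sequence[str],
    similarities: Mapping[frozenset, float],
    theta: float,
) -> nx.Graph:
    """N_PPI: link every protein pair with similarity >= theta."""
    net = nx.Graph()
    net.add_nodes_from(proteins)
    for key, sim in similarities.items():
        if sim >= theta:
            a, b = tuple(key)
            net.add_edge(a, b)
    return net


def average_degree(net: nx.Graph) -> float:
    n = net.number_of_nodes()
    return 0.0 if n == 0 else 2.0 * net.number_of_edges() / n


def select_threshold(
    similarities: Mapping[frozenset, float], n_s: nx.Graph
) -> float:
    """Choose theta_R to match N_PPI's average degree to N_S's.

    Candidates are the observed similarity values plus one value above the
    maximum (empty network).  The candidate minimizing the absolute average
    degree difference wins; ties go to the larger threshold.
    """
    if not similarities:
        raise ValueError("no similarities to threshold")
    values = sorted(set(similarities.values()))
    if len(values) == 1:
        logger.warning("all pairwise similarities equal %.4g", values[0])
    target = average_degree(n_s)
    n = n_s.number_of_nodes()
    candidates = values + [values[-1] + 1.0]
    best_theta = None
    best_err = None
    for theta in candidates:
        n_edges = sum(1 for s in similarities.values() if s >= theta)
        avg = 0.0 if n == 0 else 2.0 * n_edges / n
        err = abs(avg - target)
        if best_err is None or err < best_err or (err == best_err):
            # candidates ascend, so on ties the larger theta wins
            best_theta, best_err = theta, err
    return float(best_theta)


def topology_features(net: nx.Graph, p_i: str, p_j: str) -> np.ndarray:
    """The five link-prediction features of a pair on N_PPI.

    Proteins absent from the network are treated as isolated nodes.  An
    Adamic-Adar neighbor of degree 1 (ln 1 = 0) is skipped; 0/0 ratios
    (both neighborhoods empty) yield 0.
    """
    ni = set(net.neighbors(p_i)) if p_i in net else set()
    nj = set(net.neighbors(p_j)) if p_j in net else set()
    inter = ni & nj
    union = ni | nj
    cn = len(inter)
    jaccard = cn / len(union) if union else 0.0
    aa = 0.0
    for k in inter:
        deg = net.degree(k)
        if deg > 1:
            aa += 1.0 / math.log(deg)
        else:
            logger.debug("Adamic-Adar: skipping degree-1 neighbor %r", k)
    pa = len(ni) * len(nj)
    otsuka = cn / math.sqrt(pa) if pa > 0 else 0.0
    return np.array([cn, jaccard, aa, pa, otsuka], dtype=float)


def all_pair_similarities(
    proteins: Sequence[str],
    ic_tables: Mapping[str, IcTable],
    annotations: Mapping[str, Mapping[str, set[str]]],
) -> dict[frozenset, float]:
    """Resnik similarity for every unordered protein pair.

    ``annotations`` maps ontology -> protein -> term set.  The similarity of
    a pair is the maximum over subontologies of the protein-level Resnik
    similarity, so one threshold theta_R governs the single network.
    Term-level similarities are memoized per ontology.
    """
    term_cache: dict[str, dict[frozenset, float]] = {o: {} for o in ic_tables}

    def term_sim(ont: str, a: str, b: str) -> float:
        key = frozenset((a, b))
        cache = term_cache[ont]
        if key not in cache:
            cache[key] = resnik_term_sim(ic_tables[ont], ic_tables[ont].dag, a, b)
        return cache[key]

    sims: dict[frozenset, float] = {}
    for i, pa in enumerate(proteins):
        for pb in proteins[i + 1:]:
            best = 0.0
            for ont, ic in ic_tables.items():
                dag = ic.dag
                ta = {t for t in annotations.get(ont, {}).get(pa, set()) if t in dag}
                tb = {t for t in annotations.get(ont, {}).get(pb, set()) if t in dag}
                if ta and tb:
                    s = max(term_sim(ont, x, y) for x in ta for y in tb)
                    best = max(best, s)
            sims[frozenset((pa, pb))] = best
    return sims
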