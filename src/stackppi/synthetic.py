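"""Deterministic toy fixtures and a parameterized synthetic-data generator.

The toy fixture is a 45-term rooted DAG with five annotated training pairs
whose LCAs partition it into exactly four clusters, plus two extra pairs
whose LCA-indexed encodings are known by hand; it exercises the GO
partitioning and encoding end to end without any external ontology.

The generator emulates the statistical structure the predictor assumes:
proteins belong to functional modules anchored at deep ontology terms;
interacting pairs tend to come from the same module, so they share
annotation subgraphs (high Resnik similarity, shared LCA clusters) and a
module-specific sequence motif (a learnable composition signal).  With the
signal parameters at zero, labels are independent of all features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .go_features import GoDag
from .io import PpiDataset
from .physchem import AMINO_ACIDS

logger = logging.getLogger("stackppi")


# ---------------------------------------------------------------------------
# the 45-term toy DAG


def _toy_edges() -> list[tuple[str, str]]:
    """Child -> parent edges of the toy DAG (terms G_1..G_45, root G_1)."""
    edges = [
        # level 1
        ("G_2", "G_1"), ("G_3", "G_1"), ("G_4", "G_1"),
        # level 2
        ("G_5", "G_3"), ("G_6", "G_3"), ("G_7", "G_4"), ("G_8", "G_4"),
        ("G_9", "G_2"), ("G_10", "G_2"), ("G_11", "G_4"), ("G_12", "G_4"),
        # level 3
        ("G_13", "G_9"), ("G_14", "G_10"), ("G_15", "G_8"),
        ("G_16", "G_11"), ("G_17", "G_11"), ("G_18", "G_12"), ("G_19", "G_6"),
        # deeper terms under G_15
        ("G_20", "G_15"), ("G_21", "G_15"),
        ("G_26", "G_20"), ("G_27", "G_20"), ("G_27", "G_21"), ("G_28", "G_21"),
        ("G_33", "G_26"), ("G_34", "G_27"), ("G_35", "G_27"), ("G_36", "G_28"),
        ("G_42", "G_33"), ("G_43", "G_34"), ("G_44", "G_35"), ("G_45", "G_36"),
        # deeper terms under G_11
        ("G_22", "G_16"), ("G_23", "G_16"), ("G_23", "G_17"),
        ("G_29", "G_22"), ("G_30", "G_22"), ("G_30", "G_23"), ("G_31", "G_17"),
        ("G_37", "G_29"), ("G_38", "G_30"), ("G_39", "G_31"),
        # deeper terms under G_4 outside G_11/G_15
        ("G_24", "G_7"), ("G_25", "G_18"),
        ("G_32", "G_24"), ("G_32", "G_25"), ("G_40", "G_32"), ("G_41", "G_32"),
    ]
    return edges


#: Expected partition of the toy DAG, in carve-out (deepest-LCA-first) order.
TOY_EXPECTED_CLUSTERS: dict[str, frozenset[str]] = {
    "G_15": frozenset({
        "G_15", "G_20", "G_21", "G_26", "G_27", "G_28",
        "G_33", "G_34", "G_35", "G_36", "G_42", "G_43", "G_44", "G_45",
    }),
    "G_11": frozenset({
        "G_11", "G_16", "G_17", "G_22", "G_23", "G_29", "G_30", "G_31",
        "G_37", "G_38", "G_39",
    }),
    "G_4": frozenset({
        "G_4", "G_7", "G_8", "G_12", "G_18", "G_24", "G_25", "G_32",
        "G_40", "G_41",
    }),
    "G_1": frozenset({
        "G_1", "G_2", "G_3", "G_5", "G_6", "G_9", "G_10", "G_13", "G_14", "G_19",
    }),
}


@dataclass(frozen=True)
class ToyGoFixture:
    """The toy DAG, its five training pairs, and the expected partition."""

    dag: GoDag
    annotations: dict[str, frozenset[str]]
    training_pairs: tuple[tuple[str, str], ...]
    expected_lca_order: tuple[str, ...]
    expected_clusters: dict[str, frozenset[str]]

    def pair_terms(self) -> list[tuple[set[str], set[str]]]:
        return [
            (set(self.annotations[a]), set(self.annotations[b]))
            for a, b in self.training_pairs
        ]


def build_toy_go_fixture() -> ToyGoFixture:
    """The partitioning worked example: five pairs, four LCA clusters."""
    dag = GoDag("BP", _toy_edges())
    annotations = {
        "P1": frozenset({"G_37"}), "P2": frozenset({"G_39"}),
        "P3": frozenset({"G_24"}), "P4": frozenset({"G_25"}),
        "P5": frozenset({"G_29"}), "P6": frozenset({"G_31"}),
        "P7": frozenset({"G_42"}), "P8": frozenset({"G_45"}),
        "P9": frozenset({"G_13"}), "P10": frozenset({"G_19"}),
    }
    pairs = (("P1", "P2"), ("P3", "P4"), ("P5", "P6"), ("P7", "P8"), ("P9", "P10"))
    return ToyGoFixture(
        dag=dag,
        annotations=annotations,
        training_pairs=pairs,
        expected_lca_order=("G_15", "G_11", "G_4", "G_1"),
        expected_clusters=dict(TOY_EXPECTED_CLUSTERS),
    )


def build_toy_encoding_pairs() -> dict[tuple[str, str], tuple[set[str], set[str]]]:
    """Two extra annotated pairs with hand-derived encodings.

    On the partition of :func:`build_toy_go_fixture`, <P11,P12> encodes to
    (2, 0, 3, 4) and <P13,P14> to (0, 3, 3, 0), cluster order
    (G_15, G_11, G_4, G_1).
    """
    return {
        ("P11", "P12"): ({"G_5", "G_7", "G_20"}, {"G_6", "G_8"}),
        ("P13", "P14"): ({"G_16", "G_18"}, {"G_17"}),
    }


# ---------------------------------------------------------------------------
# random dataset generator


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic dataset generator.

    ``signal`` is the probability that an interacting pair is drawn from a
    shared functional module (and a non-interacting pair from two distinct
    modules); ``motif_rate`` the probability that a module protein carries
    its module's sequence motif; ``annotation_noise`` the per-term
    probability of replacing a module term with a uniform random term.
    ``signal = 0`` makes labels independent of every feature.
    """

    seed: int = 0
    n_proteins: int = 80
    n_terms: int = 60
    ontologies: tuple[str, ...] = ("BP", "CC", "MF")
    max_parents: int = 2
    annotations_per_protein: int = 3
    seq_length_range: tuple[int, int] = (50, 150)
    n_pairs: int = 200
    positive_fraction: float = 0.5
    n_modules: int = 4
    signal: float = 0.9
    motif_rate: float = 0.9
    annotation_noise: float = 0.05
    motif_length: int = 12
    motif_spacing: int = 8

    def __post_init__(self):
        for name in ("signal", "motif_rate", "annotation_noise", "positive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.annotations_per_protein > self.n_terms:
            raise ValueError("more annotations per protein than terms")
        if self.n_pairs > self.n_proteins * (self.n_proteins - 1) // 2:
            raise ValueError("more pairs requested than distinct protein pairs")
        if self.n_modules < 2:
            raise ValueError("need at least 2 modules")


def random_dag(ontology: str, n_terms: int, max_parents: int, rng: np.random.Generator) -> GoDag:
    """A random rooted DAG: term k attaches to 1..max_parents earlier terms."""
    names = [f"{ontology}:{k:04d}" for k in range(n_terms)]
    edges = []
    for k in range(1, n_terms):
        n_par = int(rng.integers(1, max_parents + 1))
        parents = rng.choice(k, size=min(n_par, k), replace=False)
        for p in np.atleast_1d(parents):
            edges.append((names[k], names[int(p)]))
    return GoDag(ontology, edges)


def _module_anchors(dag: GoDag, n_modules: int, rng: np.random.Generator) -> list[str]:
    """Deep anchor terms, one per module, with disjoint descendant subgraphs.

    Functional modules are meant to be distinct areas of the ontology, so
    anchors whose subgraphs overlap an already chosen module are skipped
    while possible.
    """
    candidates = sorted(
        t for t in dag.terms
        if dag.level(t) >= 2 and len(dag.descendants(t)) >= 3
    )
    if len(candidates) < n_modules:
        candidates = sorted(t for t in dag.terms if t != dag.root)
    order = rng.permutation(len(candidates))
    anchors: list[str] = []
    claimed: set[str] = set()
    for i in order:
        t = candidates[int(i)]
        if dag.descendants(t) & claimed:
            continue
        anchors.append(t)
        claimed |= dag.descendants(t)
        if len(anchors) == n_modules:
            return anchors
    for i in order:  # not enough disjoint subgraphs: allow overlap
        t = candidates[int(i)]
        if t not in anchors:
            anchors.append(t)
            if len(anchors) == n_modules:
                break
    return anchors


@dataclass(frozen=True)
class _World:
    """The shared biology: ontologies, module anchors, module motifs."""

    dags: dict[str, GoDag]
    anchors: dict[str, list[str]]
    motifs: dict[int, str]


def _generate_world(config: SyntheticConfig, rng: np.random.Generator) -> _World:
    dags: dict[str, GoDag] = {}
    anchors: dict[str, list[str]] = {}
    for ont in config.ontologies:
        dag = random_dag(ont, config.n_terms, config.max_parents, rng)
        dags[ont] = dag
        anchors[ont] = _module_anchors(dag, config.n_modules, rng)
    aa = np.array(list(AMINO_ACIDS))
    motifs = {
        m: "".join(rng.choice(aa, size=config.motif_length))
        for m in range(config.n_modules)
    }
    return _World(dags=dags, anchors=anchors, motifs=motifs)


def _populate(
    world: _World, config: SyntheticConfig, rng: np.random.Generator,
    protein_prefix: str = "SP",
) -> PpiDataset:
    ds = PpiDataset()
    ds.dags = dict(world.dags)
    anchors = world.anchors

    proteins = [f"{protein_prefix}{i:04d}" for i in range(config.n_proteins)]
    module_of = {p: i % config.n_modules for i, p in enumerate(proteins)}

    # annotations: module subgraph terms with uniform noise
    for ont, dag in ds.dags.items():
        all_terms = sorted(dag.terms)
        module_terms = [sorted(dag.descendants(a)) for a in anchors[ont]]
        per_protein: dict[str, set[str]] = {}
        for p in proteins:
            pool = module_terms[module_of[p]]
            terms: set[str] = set()
            for _ in range(config.annotations_per_protein):
                if rng.random() < config.annotation_noise or not pool:
                    terms.add(all_terms[int(rng.integers(len(all_terms)))])
                else:
                    terms.add(pool[int(rng.integers(len(pool)))])
            per_protein[p] = terms
        ds.annotations[ont] = per_protein

    # sequences: iid residues, or a periodically repeated module motif.
    # Auto-covariance only sees serial correlation, so the interaction
    # signature is a motif tiled along the sequence with random spacers:
    # module members share a lag-correlated fingerprint that the F1 block
    # can detect, while unstructured proteins have AC terms near zero.
    aa = np.array(list(AMINO_ACIDS))
    motifs = world.motifs
    lo, hi = config.seq_length_range
    for p in proteins:
        length = int(rng.integers(lo, hi + 1))
        if rng.random() < config.motif_rate:
            motif = motifs[module_of[p]]
            chunks: list[str] = []
            total = 0
            while total < length:
                spacer = "".join(rng.choice(aa, size=config.motif_spacing))
                chunks.extend([motif, spacer])
                total += config.motif_length + config.motif_spacing
            seq = "".join(chunks)[:length]
        else:
            seq = "".join(rng.choice(aa, size=length))
        ds.sequences[p] = seq

    # labeled pairs
    by_module: dict[int, list[str]] = {}
    for p in proteins:
        by_module.setdefault(module_of[p], []).append(p)
    n_pos = round(config.n_pairs * config.positive_fraction)
    used: set[frozenset] = set()

    def draw_same_module() -> tuple[str, str]:
        m = int(rng.integers(config.n_modules))
        a, b = rng.choice(len(by_module[m]), size=2, replace=False)
        return by_module[m][int(a)], by_module[m][int(b)]

    def draw_cross_module() -> tuple[str, str]:
        m1, m2 = rng.choice(config.n_modules, size=2, replace=False)
        a = by_module[int(m1)][int(rng.integers(len(by_module[int(m1)])))]
        b = by_module[int(m2)][int(rng.integers(len(by_module[int(m2)])))]
        return a, b

    def draw_uniform() -> tuple[str, str]:
        a, b = rng.choice(config.n_proteins, size=2, replace=False)
        return proteins[int(a)], proteins[int(b)]

    pairs: list[tuple[str, str, int]] = []
    attempts = 0
    while len(pairs) < config.n_pairs and attempts < 100 * config.n_pairs:
        attempts += 1
        label = 1 if len(pairs) < n_pos else 0
        with_signal = rng.random() < config.signal
        if with_signal:
            a, b = draw_same_module() if label == 1 else draw_cross_module()
        else:
            a, b = draw_uniform()
        key = frozenset((a, b))
        if key in used:
            continue
        used.add(key)
        pairs.append((a, b, label))
    if len(pairs) < config.n_pairs:
        logger.warning("generated only %d/%d pairs", len(pairs), config.n_pairs)
    order = rng.permutation(len(pairs))  # don't emit label-sorted pairs
    ds.pairs = [pairs[int(i)] for i in order]
    return ds


def generate_dataset(config: SyntheticConfig = SyntheticConfig()) -> PpiDataset:
    """Draw a synthetic PPI dataset; fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    world = _generate_world(config, rng)
    return _populate(world, config, rng)


def generate_related_datasets(
    config: SyntheticConfig, n_datasets: int = 2
) -> list[PpiDataset]:
    """Datasets sharing one ontology world but with disjoint proteins.

    Emulates different species annotated against the same (species
    independent) ontology with conserved functional modules: the DAGs,
    module anchors and module motifs are drawn once from ``config.seed``;
    each dataset then samples its own proteins, annotations, sequences and
    labeled pairs.
    """
    rng = np.random.default_rng(config.seed)
    world = _generate_world(config, rng)
    out = []
    for i in range(n_datasets):
        pop_rng = np.random.default_rng(config.seed + 10_000 * (i + 1))
        out.append(_populate(world, config, pop_rng, protein_prefix=f"S{i}P"))
    return out


def null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A label-independent (no-signal) variant of the defaults."""
    params = dict(seed=seed, signal=0.0, motif_rate=0.0, **overrides)
    return SyntheticConfig(**params)
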