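"""Readers and writers for the external formats, and the run configuration.

Formats handled: FASTA sequences (via Biopython), OBO 1.2 ontologies (via
obonet) or a minimal two-column child<TAB>parent edge-list dialect, GAF 2.x
or two-column TSV protein->term annotations, and TSV labeled protein pairs.
Pairs are unordered at the dataset level: (A, B) and (B, A) collapse to one
pair; duplicates with conflicting labels are an error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import yaml
from Bio import SeqIO

from .go_features import ONTOLOGIES, GoDag
from .physchem import ProteinRecord, sanitize_sequence

logger = logging.getLogger("stackppi")

POSITIVE_LABELS = {"1", "interacting", "positive", "true", "yes"}
NEGATIVE_LABELS = {"0", "non-interacting", "noninteracting", "negative", "false", "no"}


@dataclass
class PpiDataset:
    """Everything one experiment needs: sequences, ontologies, annotations, pairs.

    ``annotations`` maps ontology -> protein id -> set of term ids;
    ``pairs`` is a list of (protein_a, protein_b, label) with label in {0, 1}.
    """

    sequences: dict[str, str] = field(default_factory=dict)
    dags: dict[str, GoDag] = field(default_factory=dict)
    annotations: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    pairs: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def labels(self) -> list[int]:
        return [label for _, _, label in self.pairs]

    def subset(self, indices: Sequence[int]) -> "PpiDataset":
        """A view with only the selected pairs (shared sequences/ontologies)."""
        return PpiDataset(
            sequences=self.sequences,
            dags=self.dags,
            annotations=self.annotations,
            pairs=[self.pairs[i] for i in indices],
        )

    def pair_proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b, _ in self.pairs:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: str | Path, sanitize_policy: str = "drop") -> list[ProteinRecord]:
    """Read protein records from FASTA, sanitizing nonstandard residues."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = sanitize_sequence(str(rec.seq), policy=sanitize_policy)
        records.append(ProteinRecord(id=rec.id.strip(), sequence=seq))
    return records


def read_obo(path: str | Path, relations: tuple[str, ...] = ("is_a", "part_of")) -> dict[str, GoDag]:
    """Read an OBO 1.2 file into one GoDag per namespace.

    Keeps only the requested relations (``is_a`` and ``part_of`` by default)
    and drops obsolete terms (obonet already excludes them).
    """
    graph = obonet.read_obo(str(path))
    namespaces: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        namespaces[node] = data.get("namespace", "unknown")
    ns_alias = {
        "biological_process": "BP",
        "cellular_component": "CC",
        "molecular_function": "MF",
    }
    edges_by_ns: dict[str, list[tuple[str, str]]] = {}
    for child, parent, key in graph.edges(keys=True):
        if key not in relations:
            continue
        ns = ns_alias.get(namespaces.get(child, ""), namespaces.get(child, "unknown"))
        edges_by_ns.setdefault(ns, []).append((child, parent))
    return {ns: GoDag(ns, edges) for ns, edges in edges_by_ns.items()}


def read_edge_list(path: str | Path, ontology: str = "BP") -> GoDag:
    """Read the two-column child<TAB>parent fixture dialect into a GoDag."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'child<TAB>parent'")
            edges.append((parts[0].strip(), parts[1].strip()))
    return GoDag(ontology, edges)


def read_annotations_tsv(
    path: str | Path, ontology: str = "BP"
) -> dict[str, dict[str, set[str]]]:
    """Two-column protein<TAB>term annotations, optionally with a third
    ontology column."""
    annots: dict[str, dict[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 'protein<TAB>term[<TAB>ontology]'"
                )
            protein, term = parts[0].strip(), parts[1].strip()
            ont = parts[2].strip() if len(parts) == 3 else ontology
            annots.setdefault(ont, {}).setdefault(protein, set()).add(term)
    return annots


_GAF_ASPECTS = {"P": "BP", "C": "CC", "F": "MF"}


def read_gaf(
    path: str | Path, evidence_filter: set[str] | None = None
) -> dict[str, dict[str, set[str]]]:
    """GAF 2.x annotations: DB object symbol -> GO id, keyed by aspect.

    ``evidence_filter``, when given, keeps only the listed evidence codes
    (default: keep all).  NOT-qualified annotations are dropped.
    """
    annots: dict[str, dict[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                raise ValueError(f"{path}:{lineno}: GAF line has {len(cols)} columns")
            qualifier, go_id, evidence, aspect = cols[3], cols[4], cols[6], cols[8]
            if "NOT" in qualifier.split("|"):
                continue
            if evidence_filter is not None and evidence not in evidence_filter:
                continue
            ont = _GAF_ASPECTS.get(aspect)
            if ont is None:
                raise ValueError(f"{path}:{lineno}: unknown GAF aspect {aspect!r}")
            protein = cols[2].strip() or cols[1].strip()
            annots.setdefault(ont, {}).setdefault(protein, set()).add(go_id)
    return annots


def read_pairs(path: str | Path) -> list[tuple[str, str, int]]:
    """Labeled pairs TSV: protein_a<TAB>protein_b<TAB>label.

    Unordered-pair semantics: (A,B) and (B,A) duplicates collapse with a
    warning; conflicting labels raise.
    """
    seen: dict[frozenset, int] = {}
    order: list[frozenset] = []
    reps: dict[frozenset, tuple[str, str]] = {}
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'a<TAB>b<TAB>label'")
            a, b, raw = (p.strip() for p in parts)
            low = raw.lower()
            if low in POSITIVE_LABELS:
                label = 1
            elif low in NEGATIVE_LABELS:
                label = 0
            else:
                raise ValueError(f"{path}:{lineno}: unrecognized label {raw!r}")
            key = frozenset((a, b)) if a != b else frozenset((a,))
            if key in seen:
                n_dup += 1
                if seen[key] != label:
                    raise ValueError(
                        f"{path}:{lineno}: pair ({a}, {b}) duplicated with "
                        "conflicting labels"
                    )
                continue
            seen[key] = label
            order.append(key)
            reps[key] = (a, b)
    if n_dup:
        logger.warning("collapsed %d duplicate unordered pair(s)", n_dup)
    return [(reps[k][0], reps[k][1], seen[k]) for k in order]


def load_dataset(
    fasta: str | Path | None = None,
    ontology_edges: Mapping[str, str | Path] | None = None,
    obo: str | Path | None = None,
    annotations: str | Path | None = None,
    gaf: str | Path | None = None,
    pairs: str | Path | None = None,
) -> PpiDataset:
    """Assemble a dataset from files; pairs naming unknown proteins are dropped.

    A protein is known when it has a sequence or at least one annotation.
    """
    ds = PpiDataset()
    if fasta is not None:
        ds.sequences = {r.id: r.sequence for r in read_fasta(fasta)}
    if obo is not None:
        ds.dags = read_obo(obo)
    if ontology_edges:
        for ont, path in ontology_edges.items():
            ds.dags[ont] = read_edge_list(path, ontology=ont)
    if annotations is not None:
        ds.annotations = read_annotations_tsv(annotations)
    if gaf is not None:
        ds.annotations = read_gaf(gaf)
    if pairs is not None:
        raw = read_pairs(pairs)
        known = set(ds.sequences)
        for per_protein in ds.annotations.values():
            known |= set(per_protein)
        kept, dropped = [], 0
        for a, b, label in raw:
            if (not known) or (a in known and b in known):
                kept.append((a, b, label))
            else:
                dropped += 1
        if dropped:
            logger.warning("dropped %d pair(s) referencing unknown proteins", dropped)
        ds.pairs = kept
    return ds


# ---------------------------------------------------------------------------
# writers


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i: i + 60] + "\n")


def write_edge_list(dag: GoDag, path: str | Path) -> None:
    with open(path, "w") as fh:
        for child, parent in sorted(dag.graph.edges):
            fh.write(f"{child}\t{parent}\n")


def write_network_edge_list(net: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")


def write_annotations_tsv(
    annotations: Mapping[str, Mapping[str, set[str]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for ont in sorted(annotations):
            for protein in sorted(annotations[ont]):
                for term in sorted(annotations[ont][protein]):
                    fh.write(f"{protein}\t{term}\t{ont}\n")


def write_pairs(pairs: Iterable[tuple[str, str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, label in pairs:
            fh.write(f"{a}\t{b}\t{label}\n")


def write_dataset(ds: PpiDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset to a directory in the standard formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if ds.sequences:
        paths["fasta"] = out / "proteins.fasta"
        write_fasta(ds.sequences, paths["fasta"])
    for ont, dag in ds.dags.items():
        p = out / f"ontology_{ont}.tsv"
        paths[f"ontology_{ont}"] = p
        write_edge_list(dag, p)
    if ds.annotations:
        paths["annotations"] = out / "annotations.tsv"
        write_annotations_tsv(ds.annotations, paths["annotations"])
    paths["pairs"] = out / "pairs.tsv"
    write_pairs(ds.pairs, paths["pairs"])
    return paths


def read_dataset(in_dir: str | Path) -> PpiDataset:
    """Read back a directory written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    fasta = in_dir / "proteins.fasta"
    annotations = in_dir / "annotations.tsv"
    edges = {
        p.stem.removeprefix("ontology_"): p
        for p in sorted(in_dir.glob("ontology_*.tsv"))
    }
    return load_dataset(
        fasta=fasta if fasta.exists() else None,
        ontology_edges=edges or None,
        annotations=annotations if annotations.exists() else None,
        pairs=in_dir / "pairs.tsv",
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Unknown keys in a config file are rejected; the resolved copy (with all
    defaults materialized) is written into the run manifest.
    """

    feature_blocks: tuple[str, ...] = ("F1", "F2", "F3")
    ac_max_gap: int = 30
    ontologies: tuple[str, ...] | None = None
    edge_relations: tuple[str, ...] = ("is_a", "part_of")
    base_classifiers: tuple[str, ...] = ("rf", "nb", "ann", "knn")
    rf_n_estimators: int = 500
    ann_hidden_units: int = 100
    ann_max_iter: int = 200
    knn_neighbors: int = 5
    internal_folds: int = 5
    svm_c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svm_gamma_grid: tuple = ("scale", 0.01, 0.001)
    meta_cv_folds: int = 3
    cv_repeats: int = 3
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        bad = set(self.feature_blocks) - {"F1", "F2", "F3"}
        if bad:
            raise ValueError(f"unknown feature blocks: {sorted(bad)}")
        if not self.feature_blocks:
            raise ValueError("at least one feature block must be enabled")
        if self.ontologies is not None:
            bad = set(self.ontologies) - set(ONTOLOGIES)
            if bad:
                raise ValueError(f"unknown ontologies: {sorted(bad)}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = {
            k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
        }
        return cls(**coerced)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_manifest(manifest: Mapping, path: str | Path) -> None:
    def _default(o):
        import numpy as _np

        if isinstance(o, (_np.integer,)):
            return int(o)
        if isinstance(o, (_np.floating,)):
            return float(o)
        if isinstance(o, (_np.ndarray, tuple, set)):
            return list(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_default, sort_keys=True)
        fh.write("\n")
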