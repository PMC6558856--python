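"""Sequence-based physicochemical pair features (the F1 block).

Each residue of a protein is mapped to 14 physicochemical property-scale
values (two hydrophobicity scales, hydrophilicity, net charge index of the
side chain, two polarity scales, polarizability, solvent-accessible surface
area, side-chain volume, flexibility, accessibility, exposed surface, turns
and antigenic propensity).  The variable-length L x 14 profile is collapsed
into a fixed-length vector of auto-covariance (AC) terms

    AC[i, g] = 1/(L-g) * sum_{j=1..L-g} (P[i,j] - mu_i) * (P[i,j+g] - mu_i)

for each scale i and each gap g = 1..G, so that proteins of any length are
represented by 14*G numbers.  AC vectors are standardized to zero mean and
unit standard deviation feature-wise on the training set, then min-max
scaled to [0, 1].  A protein pair is represented by both concatenation
orders [V(P1)||V(P2)] and [V(P2)||V(P1)].
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("stackppi")

#: Canonical column order of the shipped scale table.
SCALE_NAMES: tuple[str, ...] = (
    "H11", "H12", "H2", "NCI", "P11", "P12", "P2",
    "SASA", "V", "F", "A1", "E", "T", "A2",
)

N_SCALES = len(SCALE_NAMES)

#: The 20 essential amino acids, alphabetical one-letter codes.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Residue codes that may appear in real FASTA records but carry no scale
#: values (ambiguity codes, selenocysteine/pyrrolysine, stop).
NONSTANDARD_RESIDUES: frozenset[str] = frozenset("BZXUO*")


class PhyschemScaleTable:
    """The 20 x 14 matrix of amino-acid property-scale values.

    Rows are amino acids (one-letter codes), columns the 14 scales in the
    canonical :data:`SCALE_NAMES` order.
    """

    def __init__(self, frame: pd.DataFrame):
        missing_aa = set(AMINO_ACIDS) - set(frame.index)
        if missing_aa:
            raise ValueError(f"scale table missing amino acids: {sorted(missing_aa)}")
        if list(frame.columns) != list(SCALE_NAMES):
            raise ValueError("scale table columns must match the canonical scale order")
        if frame.isna().any().any():
            raise ValueError("scale table contains empty cells")
        self.frame = frame.loc[list(AMINO_ACIDS), list(SCALE_NAMES)].astype(float)
        self._vectors = {aa: self.frame.loc[aa].to_numpy() for aa in AMINO_ACIDS}

    @classmethod
    def default(cls) -> "PhyschemScaleTable":
        """Load the scale table shipped with the package."""
        ref = importlib.resources.files("stackppi").joinpath("data/aa_scales.tsv")
        with importlib.resources.as_file(ref) as path:
            frame = pd.read_csv(path, sep="\t", index_col="AA")
        return cls(frame)

    @property
    def scales(self) -> tuple[str, ...]:
        return SCALE_NAMES

    def vector(self, residue: str) -> np.ndarray:
        """The 14 scale values of one residue, in canonical order."""
        try:
            return self._vectors[residue]
        except KeyError:
            raise KeyError(f"no scale values for residue {residue!r}") from None


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its amino-acid sequence."""

    id: str
    sequence: str


@dataclass(frozen=True)
class AcConfig:
    """Auto-covariance settings: ``max_gap`` is G; gaps run 1..G."""

    max_gap: int = 30

    def __post_init__(self):
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")


@dataclass(frozen=True)
class AcVector:
    """AC encoding of one protein: 14*G values, scale-major then gap."""

    protein_id: str
    values: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.values)


def sanitize_sequence(sequence: str, policy: str = "drop") -> str:
    """Remove or reject residues outside the 20 essentials.

    policy="drop" silently removes nonstandard residues (B, Z, X, U, O, *)
    with a log warning; policy="error" raises on the first offending symbol,
    reporting it with its 1-based position.
    """
    seq = sequence.strip().upper()
    valid = set(AMINO_ACIDS)
    bad = [(j, ch) for j, ch in enumerate(seq, start=1) if ch not in valid]
    if not bad:
        return seq
    if policy == "error":
        j, ch = bad[0]
        raise ValueError(f"unknown residue {ch!r} at position {j}")
    if policy == "drop":
        dropped = "".join(sorted({ch for _, ch in bad}))
        logger.warning("dropped %d nonstandard residue(s) (%s)", len(bad), dropped)
        return "".join(ch for ch in seq if ch in valid)
    raise ValueError(f"unknown sanitization policy {policy!r}")


def translate_sequence(protein: ProteinRecord, table: PhyschemScaleTable) -> np.ndarray:
    """Translate a protein into its L x 14 physicochemical profile.

    Row j holds the 14 scale values of residue j in canonical scale order.
    The sequence must already be sanitized (only the 20 essentials).
    """
    if not protein.sequence:
        raise ValueError(f"protein {protein.id!r} has an empty sequence")
    return np.array([table.vector(ch) for ch in protein.sequence])


def auto_covariance(scale_values: np.ndarray, gap: int) -> float:
    """Lag-``gap`` auto-covariance of one scale profile.

    Returns 0.0 when ``gap >= L`` (empty-sum convention), so short proteins
    still produce full-length AC vectors.
    """
    if gap < 1:
        raise ValueError("gap must be >= 1")
    values = np.asarray(scale_values, dtype=float)
    length = values.size
    if gap >= length:
        return 0.0
    mu = values.mean()
    dev = values - mu
    return float(dev[: length - gap] @ dev[gap:] / (length - gap))


def encode_protein(
    protein: ProteinRecord,
    table: PhyschemScaleTable,
    config: AcConfig = AcConfig(),
) -> AcVector:
    """Encode a protein as its 14*G AC vector.

    Ordering is scale-major: (scale 1, g=1), (scale 1, g=2), ...,
    (scale 14, g=G).  The length is 14*G regardless of sequence length.
    """
    profile = translate_sequence(protein, table)
    gaps = range(1, config.max_gap + 1)
    values = np.array(
        [auto_covariance(profile[:, i], g) for i in range(N_SCALES) for g in gaps]
    )
    return AcVector(protein_id=protein.id, values=values)


class Normalizer:
    """Feature-wise standardization followed by min-max scaling to [0, 1].

    Both stages are fitted on training data only.  Zero-variance features
    use SD := 1 (so they become centered constants), zero-range features
    scale to 0, and values outside the training range are clipped to [0, 1].
    """

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None
        self.min_: np.ndarray | None = None
        self.max_: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        if self.mean_ is None:
            raise RuntimeError("normalizer is not fitted")
        return self.mean_.size

    def fit(self, X: np.ndarray) -> "Normalizer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < 2:
            raise ValueError("fitting the normalizer requires >= 2 training vectors")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd == 0.0, 1.0, sd)
        S = (X - self.mean_) / self.sd_
        self.min_ = S.min(axis=0)
        self.max_ = S.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("normalizer is not fitted")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        S = (X - self.mean_) / self.sd_
        span = self.max_ - self.min_
        V = np.where(span == 0.0, 0.0, (S - self.min_) / np.where(span == 0.0, 1.0, span))
        V = np.clip(V, 0.0, 1.0)
        return V[0] if single else V

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def fit_normalizer(vectors: list[AcVector]) -> Normalizer:
    """Fit a :class:`Normalizer` on a training collection of AC vectors."""
    return Normalizer().fit(np.array([v.values for v in vectors]))


def apply_normalizer(stats: Normalizer, vector: AcVector) -> AcVector:
    return AcVector(protein_id=vector.protein_id, values=stats.transform(vector.values))


def pair_vectors(v1: np.ndarray, v2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Both concatenation orders of a protein pair's feature vectors.

    Returns ([v1||v2], [v2||v1]); training uses both as separate instances
    with the same label, prediction averages over both orders.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError(f"length mismatch: {v1.shape} vs {v2.shape}")
    return np.concatenate([v1, v2]), np.concatenate([v2, v1])
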