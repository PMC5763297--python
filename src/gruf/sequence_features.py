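"""Sequence featurization and similarity construction.

lncRNA sequences are described by segmented k-mer occurrence frequencies:
a sequence is split into ``n_segments`` contiguous blocks of approximately
equal length, the 4-mer frequency vector is computed per block and the blocks
are concatenated (35 segments x 4^4 = 8960 dimensions).  Segmentation captures
that RNA-protein binding is local in sequence.

Protein sequences are first recoded into a 7-letter reduced alphabet (amino
acids grouped by dipole moment and side-chain volume) and then described by
3-mer frequencies on the recoded sequence (7^3 = 343 dimensions).

Feature matrices are column-standardized (Z-score), optionally compressed by
PCA (dropping numerically-zero directions), and turned into similarities via
s_ij = 1 / (1 + ||f_i - f_j||_2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import FeatureMatrix, SimilarityMatrix

__all__ = [
    "RNA_ALPHABET",
    "PROTEIN_GROUPS",
    "PROTEIN_GROUP_ALPHABET",
    "RnaSequence",
    "ProteinSequence",
    "kmer_frequency",
    "segmented_kmer_features",
    "encode_protein_sequence",
    "protein_kmer_features",
    "zscore_columns",
    "pca_reduce",
    "similarity_from_features",
    "rna_feature_matrix",
    "protein_feature_matrix",
    "sequence_similarity",
    "SegmentedKmerFeaturizer",
]

RNA_ALPHABET = "ACGU"

#: Amino-acid groups by dipole moment and side-chain volume; group index is
#: the 1-based position in this tuple.
PROTEIN_GROUPS = (
    "AGV",      # 1
    "ILFP",     # 2
    "YMTS",     # 3
    "HNQW",     # 4
    "RK",       # 5
    "DE",       # 6
    "C",        # 7
)
PROTEIN_GROUP_ALPHABET = "1234567"
_AA_TO_GROUP = {
    aa: str(g + 1) for g, members in enumerate(PROTEIN_GROUPS) for aa in members
}
AMINO_ACIDS = frozenset(_AA_TO_GROUP)


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A, C, G, U}; DNA-style T and lowercase accepted."""

    id: str
    residues: str

    def __post_init__(self):
        res = self.residues.upper().replace("T", "U")
        if not res:
            raise ValueError(f"RNA sequence {self.id!r} is empty")
        bad = set(res) - set(RNA_ALPHABET)
        if bad:
            raise ValueError(
                f"RNA sequence {self.id!r} contains invalid symbols {sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20 standard one-letter amino-acid codes."""

    id: str
    residues: str

    def __post_init__(self):
        res = self.residues.upper()
        if not res:
            raise ValueError(f"protein sequence {self.id!r} is empty")
        for pos, aa in enumerate(res, start=1):
            if aa not in AMINO_ACIDS:
                raise ValueError(
                    f"protein sequence {self.id!r}: invalid residue {aa!r} "
                    f"at position {pos}"
                )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)


def kmer_frequency(seq, k: int, alphabet: str | Sequence[str] = RNA_ALPHABET) -> np.ndarray:
    """Overlapping k-mer occurrence frequencies, lexicographic in `alphabet`.

    Counts every window of length ``k`` at step 1 and divides by the number of
    windows (len - k + 1), so the output sums to one.
    """
    if k < 1:
        raise ValueError(f"k must be positive, got {k}")
    residues = seq.residues if hasattr(seq, "residues") else str(seq)
    alphabet = tuple(alphabet)
    base = len(alphabet)
    index = {c: i for i, c in enumerate(alphabet)}
    n_windows = len(residues) - k + 1
    if n_windows < 1:
        name = getattr(seq, "id", None)
        label = f" ({name})" if name else ""
        raise ValueError(
            f"sequence of length {len(residues)}{label} is shorter than k={k}: "
            "segment unusable"
        )
    try:
        codes = np.array([index[c] for c in residues], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} not in alphabet {alphabet}") from None
    # polynomial rolling encoding of each window
    weights = base ** np.arange(k - 1, -1, -1, dtype=np.int64)
    slots = np.lib.stride_tricks.sliding_window_view(codes, k) @ weights
    counts = np.bincount(slots, minlength=base**k).astype(float)
    return counts / n_windows


def _segment_bounds(length: int, n_segments: int) -> list[tuple[int, int]]:
    """Left-to-right split: the first (length mod s) segments get the extra residue."""
    base, extra = divmod(length, n_segments)
    bounds, start = [], 0
    for i in range(n_segments):
        size = base + (1 if i < extra else 0)
        bounds.append((start, start + size))
        start += size
    return bounds


def segmented_kmer_features(
    seq: RnaSequence, k: int = 4, n_segments: int = 35
) -> np.ndarray:
    """Concatenated per-segment k-mer frequencies (each block sums to 1)."""
    if n_segments < 1:
        raise ValueError(f"n_segments must be positive, got {n_segments}")
    residues = seq.residues if hasattr(seq, "residues") else str(seq)
    if len(residues) < n_segments * k:
        name = getattr(seq, "id", "<anonymous>")
        raise ValueError(
            f"sequence {name!r} of length {len(residues)} too short for "
            f"{n_segments} segments of >= {k} residues"
        )
    blocks = [
        kmer_frequency(residues[a:b], k, RNA_ALPHABET)
        for a, b in _segment_bounds(len(residues), n_segments)
    ]
    return np.concatenate(blocks)


def encode_protein_sequence(seq: ProteinSequence | str) -> str:
    """Recode a protein sequence into the 7-letter group alphabet."""
    residues = seq.residues if hasattr(seq, "residues") else str(seq).upper()
    out = []
    for pos, aa in enumerate(residues, start=1):
        group = _AA_TO_GROUP.get(aa)
        if group is None:
            raise ValueError(f"invalid residue {aa!r} at position {pos}")
        out.append(group)
    return "".join(out)


def protein_kmer_features(seq: ProteinSequence | str, k: int = 3) -> np.ndarray:
    """k-mer frequencies of the group-encoded protein sequence (7^k dims)."""
    return kmer_frequency(encode_protein_sequence(seq), k, PROTEIN_GROUP_ALPHABET)


def zscore_columns(fm: FeatureMatrix) -> FeatureMatrix:
    """Standardize columns to mean 0 / sample std 1 (ddof=1).

    Zero-variance columns are mapped to all-zero rather than NaN so that
    downstream distances stay finite.
    """
    x = fm.values
    if x.shape[0] < 2:
        raise ValueError("Z-score needs at least 2 rows (sample std undefined)")
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=1)
    out = np.zeros_like(x)
    nz = std > 0
    out[:, nz] = (x[:, nz] - mean[nz]) / std[nz]
    return FeatureMatrix(fm.ids, out)


def pca_reduce(fm: FeatureMatrix, component_rule=None) -> FeatureMatrix:
    """Project rows onto the principal components that are not numerically zero.

    `component_rule` is either None (default: keep components with singular
    value > 1e-10 x largest), an int (keep that many leading components) or a
    float (relative singular-value tolerance).  Pairwise Euclidean distances
    are preserved exactly when no component is dropped (pure rotation).
    """
    x = fm.values - fm.values.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if isinstance(component_rule, (int, np.integer)) and not isinstance(
        component_rule, bool
    ):
        keep = min(int(component_rule), len(s))
    else:
        tol = 1e-10 if component_rule is None else float(component_rule)
        smax = s[0] if len(s) else 0.0
        keep = int(np.sum(s > tol * smax)) if smax > 0 else 0
    return FeatureMatrix(fm.ids, x @ vt[:keep].T)


def similarity_from_features(fm: FeatureMatrix) -> SimilarityMatrix:
    """Pairwise similarity s_ij = 1 / (1 + Euclidean distance)."""
    if fm.values.shape[0] == 0:
        raise ValueError("cannot build a similarity matrix from 0 rows")
    if fm.values.shape[0] == 1:
        return SimilarityMatrix(fm.ids, np.ones((1, 1)))
    dist = squareform(pdist(fm.values, metric="euclidean"))
    sim = 1.0 / (1.0 + dist)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(fm.ids, sim)


def rna_feature_matrix(
    seqs: Iterable[RnaSequence], k: int = 4, n_segments: int = 35
) -> FeatureMatrix:
    seqs = list(seqs)
    values = np.vstack([segmented_kmer_features(s, k, n_segments) for s in seqs])
    return FeatureMatrix(tuple(s.id for s in seqs), values)


def protein_feature_matrix(seqs: Iterable[ProteinSequence], k: int = 3) -> FeatureMatrix:
    seqs = list(seqs)
    values = np.vstack([protein_kmer_features(s, k) for s in seqs])
    return FeatureMatrix(tuple(s.id for s in seqs), values)


def sequence_similarity(
    seqs: Sequence[RnaSequence] | Sequence[ProteinSequence],
    *,
    k: int | None = None,
    n_segments: int = 35,
    zscore: bool = True,
    pca: bool = True,
    component_rule=None,
) -> SimilarityMatrix:
    """Full pipeline: (segmented) k-mer features -> Z-score -> PCA -> 1/(1+dist).

    RNA sequences get segmented 4-mer features; protein sequences get 3-mer
    features on the 7-group encoding.  The pipeline order is fixed.
    """
    first = seqs[0]
    if isinstance(first, RnaSequence):
        fm = rna_feature_matrix(seqs, k or 4, n_segments)
    elif isinstance(first, ProteinSequence):
        fm = protein_feature_matrix(seqs, k or 3)
    else:
        raise TypeError(f"unsupported sequence type {type(first).__name__}")
    if zscore:
        fm = zscore_columns(fm)
    if pca:
        fm = pca_reduce(fm, component_rule)
    return similarity_from_features(fm)


class SegmentedKmerFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer from sequences to (optionally standardized/compressed)
    segmented k-mer feature rows; composes with sklearn pipelines.

    Parameters
    ----------
    k : k-mer length (4 for RNA, 3 for group-encoded proteins).
    n_segments : number of approximately equal-length segments (RNA only).
    zscore, pca : apply column standardization / zero-direction removal.
    component_rule : forwarded to :func:`pca_reduce`.
    """

    def __init__(self, k=4, n_segments=35, zscore=True, pca=True, component_rule=None):
        self.k = k
        self.n_segments = n_segments
        self.zscore = zscore
        self.pca = pca
        self.component_rule = component_rule

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        seqs = list(X)
        if not seqs:
            raise ValueError("empty sequence collection")
        if isinstance(seqs[0], ProteinSequence):
            fm = protein_feature_matrix(seqs, self.k if self.k != 4 else 3)
        else:
            fm = rna_feature_matrix(seqs, self.k, self.n_segments)
        if self.zscore:
            fm = zscore_columns(fm)
        if self.pca:
            fm = pca_reduce(fm, self.component_rule)
        return fm.values
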