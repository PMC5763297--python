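"""Construction of binary, discrete and continued association matrices.

Starting from a binary lncRNA x protein interaction matrix and a binary
gene x disease association matrix (genes and the proteins they encode are
treated as one namespace), three variants of the lncRNA x disease matrix are
derived:

* binary    -- 1 iff the lncRNA and the disease share at least one gene;
* discrete  -- the number of shared genes;
* continued -- A_rp . S_P . A_gd, weighting each shared-gene path by protein
               similarity, so that more and more-similar shared proteins give
               a stronger association intensity.

With S_P = I the continued matrix collapses exactly to the discrete one, and
binarizing the discrete matrix reproduces the binary one.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import BipartiteMatrix, LdaMatrix, SimilarityMatrix

__all__ = [
    "build_binary",
    "build_discrete",
    "build_continued",
    "binarize",
    "labels_from_binary",
]

logger = logging.getLogger(__name__)


def _shared_genes(a_rp: BipartiteMatrix, a_gd: BipartiteMatrix) -> list[str]:
    """Intersection of the protein-coding genes and disease-associated genes.

    Order follows the lncRNA-protein matrix columns; dropped genes are logged.
    """
    gd_rows = set(a_gd.row_ids)
    shared = [g for g in a_rp.col_ids if g in gd_rows]
    if not shared:
        raise ValueError(
            "no shared gene/protein namespace between the lncRNA-protein "
            "columns and the gene-disease rows"
        )
    dropped = (len(a_rp.col_ids) - len(shared)) + (len(a_gd.row_ids) - len(shared))
    if dropped:
        logger.warning(
            "dropping %d genes outside the shared namespace (%d kept)",
            dropped,
            len(shared),
        )
    return shared


def _aligned(a_rp: BipartiteMatrix, a_gd: BipartiteMatrix):
    genes = _shared_genes(a_rp, a_gd)
    rp_pos = {g: i for i, g in enumerate(a_rp.col_ids)}
    gd_pos = {g: i for i, g in enumerate(a_gd.row_ids)}
    idx_rp = np.array([rp_pos[g] for g in genes])
    idx_gd = np.array([gd_pos[g] for g in genes])
    return genes, a_rp.values[:, idx_rp], a_gd.values[idx_gd, :]


def build_discrete(a_rp: BipartiteMatrix, a_gd: BipartiteMatrix) -> LdaMatrix:
    """Count shared genes: a(i,j) = |{g : lncRNA i binds g and g is linked to j}|."""
    _, rp, gd = _aligned(a_rp, a_gd)
    counts = (rp > 0).astype(float) @ (gd > 0).astype(float)
    return LdaMatrix(a_rp.row_ids, a_gd.col_ids, np.round(counts), "discrete")


def build_binary(a_rp: BipartiteMatrix, a_gd: BipartiteMatrix) -> LdaMatrix:
    """Indicator of sharing at least one gene."""
    discrete = build_discrete(a_rp, a_gd)
    return LdaMatrix(
        discrete.lncrna_ids,
        discrete.disease_ids,
        (discrete.values > 0).astype(float),
        "binary",
    )


def build_continued(
    a_rp: BipartiteMatrix, s_p: SimilarityMatrix, a_gd: BipartiteMatrix
) -> LdaMatrix:
    """Similarity-weighted association intensity A_rp . S_P . A_gd.

    S_P is restricted to the shared gene namespace; every gene in the
    intersection must be present in S_P.
    """
    genes, rp, gd = _aligned(a_rp, a_gd)
    sp = s_p.subset(genes)
    values = rp @ sp.values @ gd
    return LdaMatrix(a_rp.row_ids, a_gd.col_ids, values, "continued")


def binarize(lda: LdaMatrix, threshold: float = 0.0) -> LdaMatrix:
    """Binary view of any association variant (entry > threshold -> 1)."""
    return LdaMatrix(
        lda.lncrna_ids,
        lda.disease_ids,
        (lda.values > threshold).astype(float),
        "binary",
    )


def labels_from_binary(lda: LdaMatrix, bam: LdaMatrix) -> np.ndarray:
    """Binary labels for entries of a discrete/continued matrix.

    Each entry of the binary association matrix labels the corresponding
    entry of the richer matrix, enabling ROC analysis of non-binary scores.
    """
    if bam.variant != "binary":
        raise ValueError(f"labels must come from a binary matrix, got {bam.variant!r}")
    if lda.lncrna_ids != bam.lncrna_ids or lda.disease_ids != bam.disease_ids:
        raise ValueError("association and label matrices have different id sets")
    return bam.values.copy()
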