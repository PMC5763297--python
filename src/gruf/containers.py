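"""Labelled matrix containers shared across the pipeline.

All matrices carry explicit row/column identifiers; positional indices are an
internal detail.  Construction validates the invariants of each matrix class
(symmetry and unit diagonal for similarities, value domains for association
matrices), so a container that exists is a container that is well formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "SimilarityMatrix",
    "BipartiteMatrix",
    "LdaMatrix",
    "ScoreMatrix",
    "LDA_VARIANTS",
]

LDA_VARIANTS = ("binary", "discrete", "continued")

_SYM_TOL = 1e-8
_DIAG_TOL = 1e-12


def _as_ids(ids: Iterable, what: str) -> tuple[str, ...]:
    out = tuple(str(i) for i in ids)
    if len(set(out)) != len(out):
        seen, dups = set(), []
        for i in out:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dups))}")
    return out


def _as_values(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{what} values must be 2-D, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{what} values contain non-finite entries")
    return arr


@dataclass(frozen=True)
class FeatureMatrix:
    """Dense entity x feature matrix with ordered row identifiers."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids", _as_ids(self.ids, "row"))
        object.__setattr__(self, "values", _as_values(self.values, "feature"))
        if len(self.ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids for {self.values.shape[0]} feature rows"
            )

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(tuple(map(str, df.index)), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric similarity matrix with unit diagonal and entries in [0, 1].

    Sequence-derived similarities (1/(1+dist)) are strictly positive; semantic
    disease similarities may contain exact zeros (disjoint descriptor graphs),
    so the admissible range is the closed interval.
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids", _as_ids(self.ids, "entity"))
        object.__setattr__(self, "values", _as_values(self.values, "similarity"))
        v = self.values
        if v.shape[0] != v.shape[1]:
            raise ValueError(f"similarity matrix must be square, got {v.shape}")
        if len(self.ids) != v.shape[0]:
            raise ValueError(f"{len(self.ids)} ids for shape {v.shape}")
        asym = float(np.max(np.abs(v - v.T))) if v.size else 0.0
        if asym > _SYM_TOL:
            raise ValueError(f"similarity matrix asymmetric (max |S-S'T| = {asym:g})")
        if v.size and np.max(np.abs(np.diag(v) - 1.0)) > _DIAG_TOL:
            raise ValueError("similarity diagonal must be exactly 1")
        if v.size and (v.min() < -_DIAG_TOL or v.max() > 1.0 + _DIAG_TOL):
            raise ValueError("similarity entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SimilarityMatrix":
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError("similarity matrix row and column labels differ")
        return cls(tuple(map(str, df.index)), df.to_numpy(dtype=float))

    def subset(self, ids: Sequence[str]) -> "SimilarityMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"ids absent from similarity matrix: {missing}")
        idx = np.array([pos[i] for i in ids])
        return SimilarityMatrix(tuple(ids), self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class BipartiteMatrix:
    """Non-negative labelled matrix between two entity sets.

    Houses the lncRNA x protein interaction matrix and the (gene x disease
    oriented) gene-disease association matrix.
    """

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "row_ids", _as_ids(self.row_ids, "row"))
        object.__setattr__(self, "col_ids", _as_ids(self.col_ids, "column"))
        object.__setattr__(self, "values", _as_values(self.values, "bipartite"))
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.row_ids)} x {len(self.col_ids)} labels"
            )
        if self.values.size and self.values.min() < 0:
            raise ValueError("bipartite matrix entries must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_ids), columns=list(self.col_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BipartiteMatrix":
        return cls(
            tuple(map(str, df.index)),
            tuple(map(str, df.columns)),
            df.to_numpy(dtype=float),
        )


def _validate_variant(values: np.ndarray, variant: str) -> None:
    if variant == "binary":
        if not np.isin(values, (0.0, 1.0)).all():
            bad = np.unique(values[~np.isin(values, (0.0, 1.0))])[:5]
            raise ValueError(f"binary association matrix has entries {bad}")
    elif variant == "discrete":
        if values.size and (values.min() < 0 or np.any(values != np.round(values))):
            raise ValueError("discrete association matrix must hold counts (N0)")
    elif variant == "continued":
        if values.size and values.min() < 0:
            raise ValueError("continued association matrix must be non-negative")
    else:
        raise ValueError(f"unknown association variant {variant!r}; "
                         f"expected one of {LDA_VARIANTS}")


@dataclass(frozen=True)
class LdaMatrix:
    """lncRNA x disease association matrix in one of three variants.

    binary    -- 0/1 indicator of a known association
    discrete  -- number of shared proteins/coding genes (counts)
    continued -- real-valued association intensity (>= 0)
    """

    lncrna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    values: np.ndarray
    variant: str

    def __post_init__(self):
        object.__setattr__(self, "lncrna_ids", _as_ids(self.lncrna_ids, "lncRNA"))
        object.__setattr__(self, "disease_ids", _as_ids(self.disease_ids, "disease"))
        object.__setattr__(self, "values", _as_values(self.values, "association"))
        if self.values.shape != (len(self.lncrna_ids), len(self.disease_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.lncrna_ids)} x {len(self.disease_ids)} labels"
            )
        _validate_variant(self.values, self.variant)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.lncrna_ids), columns=list(self.disease_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, variant: str) -> "LdaMatrix":
        return cls(
            tuple(map(str, df.index)),
            tuple(map(str, df.columns)),
            df.to_numpy(dtype=float),
            variant,
        )


@dataclass(frozen=True)
class ScoreMatrix:
    """Predicted confidence scores for lncRNA-disease pairs."""

    lncrna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lncrna_ids", _as_ids(self.lncrna_ids, "lncRNA"))
        object.__setattr__(self, "disease_ids", _as_ids(self.disease_ids, "disease"))
        object.__setattr__(self, "scores", _as_values(self.scores, "score"))
        if self.scores.shape != (len(self.lncrna_ids), len(self.disease_ids)):
            raise ValueError("score matrix shape inconsistent with labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=list(self.lncrna_ids), columns=list(self.disease_ids)
        )
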