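"""Readers and writers for the package's on-disk formats.

Sequences travel as FASTA; every matrix is a labelled TSV (first row =
column labels, first column = row labels, full-precision decimals) so that
fixtures stay diffable.  Type invariants are enforced on load: a file that
reads successfully yields a valid container.  Fitted models serialize to a
directory of labelled TSVs plus a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import (
    BipartiteMatrix,
    FeatureMatrix,
    LdaMatrix,
    ScoreMatrix,
    SimilarityMatrix,
)
from .disease_semantics import MeshHierarchy
from .graph_regression import Embedding, GrufRegressor
from .sequence_features import ProteinSequence, RnaSequence

__all__ = [
    "read_fasta",
    "read_rna_fasta",
    "read_protein_fasta",
    "write_fasta",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_hierarchy_tsv",
    "write_hierarchy_tsv",
    "read_descriptors_tsv",
    "write_descriptors_tsv",
    "save_model",
    "load_model",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """Ordered (id, residues) records; id = first whitespace-delimited token."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_rna_fasta(path) -> list[RnaSequence]:
    return [RnaSequence(i, s) for i, s in read_fasta(path)]


def read_protein_fasta(path) -> list[ProteinSequence]:
    return [ProteinSequence(i, s) for i, s in read_fasta(path)]


def write_fasta(path, seqs: Iterable, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            sid = seq[0] if isinstance(seq, tuple) else seq.id
            res = seq[1] if isinstance(seq, tuple) else seq.residues
            fh.write(f">{sid}\n")
            for i in range(0, len(res), width):
                fh.write(res[i : i + width] + "\n")


def _read_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged rows or missing values")
    return df


def read_matrix_tsv(path, expect: str, variant: str | None = None):
    """Load a labelled TSV as a typed matrix, enforcing the type's invariants.

    ``expect`` is one of 'similarity', 'bipartite', 'lda', 'feature',
    'scores'; ``variant`` names the association variant for 'lda'.
    """
    df = _read_frame(path)
    try:
        if expect == "similarity":
            return SimilarityMatrix.from_frame(df)
        if expect == "bipartite":
            return BipartiteMatrix.from_frame(df)
        if expect == "lda":
            if variant is None:
                raise ValueError("loading an association matrix requires a variant")
            return LdaMatrix.from_frame(df, variant)
        if expect == "feature":
            return FeatureMatrix.from_frame(df)
        if expect == "scores":
            return ScoreMatrix(
                tuple(map(str, df.index)),
                tuple(map(str, df.columns)),
                df.to_numpy(dtype=float),
            )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None
    raise ValueError(f"unknown matrix kind {expect!r}")


def write_matrix_tsv(path, matrix) -> None:
    df = matrix.to_frame()
    df.to_csv(path, sep="\t", index_label="")


def read_hierarchy_tsv(path) -> MeshHierarchy:
    """Two-column child_code<TAB>parent_code edge list."""
    edges = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 columns, got {len(parts)}")
            edges.append((parts[0], parts[1]))
    return MeshHierarchy(edges)


def write_hierarchy_tsv(path, edges: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for child, parent in edges:
            fh.write(f"{child}\t{parent}\n")


def read_descriptors_tsv(path) -> dict[str, tuple[str, ...]]:
    """disease_id<TAB>comma-separated descriptor codes."""
    out: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 columns")
            if parts[0] in out:
                raise ValueError(f"{path}:{line_no}: duplicate disease {parts[0]!r}")
            out[parts[0]] = tuple(c.strip() for c in parts[1].split(",") if c.strip())
    return out


def write_descriptors_tsv(path, assignments: Mapping[str, tuple[str, ...]]) -> None:
    with open(path, "w") as fh:
        for disease, codes in assignments.items():
            fh.write(f"{disease}\t{','.join(codes)}\n")


def _embedding_frames(emb: Embedding) -> tuple[pd.DataFrame, pd.DataFrame]:
    factors = pd.DataFrame(emb.factors, index=list(emb.ids))
    spectrum = pd.DataFrame({"singular_value": emb.singular_values})
    return factors, spectrum


def save_model(model: GrufRegressor, directory) -> None:
    """Serialize a fitted model as labelled TSVs plus a JSON manifest."""
    model._check_fitted()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, emb in (("ra", model.ra_), ("da", model.da_), ("fr", model.fr_), ("fd", model.fd_)):
        factors, spectrum = _embedding_frames(emb)
        factors.to_csv(directory / f"{name}_factors.tsv", sep="\t", index_label="")
        spectrum.to_csv(directory / f"{name}_spectrum.tsv", sep="\t", index=False)
    for name, mat in (("br", model.br_), ("bd", model.bd_), ("theta", model.theta_)):
        pd.DataFrame(mat).to_csv(directory / f"{name}.tsv", sep="\t", index_label="")
    manifest = {
        "format_version": 1,
        "params": model.get_params(),
        "ranks": list(model.ranks_),
        "lncrna_ids": list(model.lncrna_ids_),
        "disease_ids": list(model.disease_ids_),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _load_embedding(directory: Path, name: str) -> Embedding:
    factors = pd.read_csv(directory / f"{name}_factors.tsv", sep="\t", index_col=0, float_precision="round_trip")
    spectrum = pd.read_csv(directory / f"{name}_spectrum.tsv", sep="\t", float_precision="round_trip")
    return Embedding(
        tuple(map(str, factors.index)),
        factors.to_numpy(dtype=float),
        spectrum["singular_value"].to_numpy(dtype=float),
    )


def load_model(directory) -> GrufRegressor:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    model = GrufRegressor(**manifest["params"])
    model.ra_ = _load_embedding(directory, "ra")
    model.da_ = _load_embedding(directory, "da")
    model.fr_ = _load_embedding(directory, "fr")
    model.fd_ = _load_embedding(directory, "fd")
    model.br_ = pd.read_csv(directory / "br.tsv", sep="\t", index_col=0, float_precision="round_trip").to_numpy(float)
    model.bd_ = pd.read_csv(directory / "bd.tsv", sep="\t", index_col=0, float_precision="round_trip").to_numpy(float)
    model.theta_ = pd.read_csv(directory / "theta.tsv", sep="\t", index_col=0, float_precision="round_trip").to_numpy(float)
    model.ranks_ = tuple(manifest["ranks"])
    model.lncrna_ids_ = tuple(manifest["lncrna_ids"])
    model.disease_ids_ = tuple(manifest["disease_ids"])
    return model
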