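"""Graph regression core: low-rank embeddings, PLS bi-regression, predictors.

The association graph and the two similarity graphs are each mapped into a
latent space by a truncated spectral factorization:

* the m x n association matrix A is factored by SVD into an m x r lncRNA
  associating matrix A_r = U sqrt(S) and an n x r disease associating matrix
  A_d = V sqrt(S), so that A ~ A_r A_d';
* each symmetric similarity matrix S is factored into latent features
  F = U sqrt(L+) over its leading non-negative eigenvalues, so S ~ F F'.

Two multi-response partial least squares regressions map the latent feature
spaces into the associating space (B_r : F_r -> A_r, B_d : F_d -> A_d); their
product Theta = B_r B_d' is the bi-regression matrix linking lncRNA features
to disease features.  Predicted confidence scores are the bilinear forms

    T1: F_r Theta F_d'      (known lncRNAs x known diseases)
    T2: F_rx Theta F_d'     (new lncRNAs, embedded from similarity rows)
    T3: F_r Theta F_dy'     (new diseases)
    T4: F_rx Theta F_dy'    (both new: double cold start)

where a new entity's latent row is the Nystrom projection s_x U S^(-1/2) of
its similarity row to the training entities.  PLS is deliberately uncentered:
the predictors carry no intercept, so the regression must be raw bilinear
algebra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .containers import LdaMatrix, ScoreMatrix, SimilarityMatrix

__all__ = [
    "Embedding",
    "svd_embed",
    "symmetric_embed",
    "pls_regress",
    "project_similarity_rows",
    "GrufRegressor",
    "fit",
]

_RANK_TOL = 1e-10
_SYM_TOL = 1e-8


@dataclass(frozen=True)
class Embedding:
    """Spectral embedding of one entity set.

    ``factors`` holds U sqrt(sigma); ``singular_values`` the retained
    spectrum, non-increasing and non-negative.
    """

    ids: tuple[str, ...]
    factors: np.ndarray
    singular_values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "factors", np.asarray(self.factors, dtype=float))
        object.__setattr__(
            self, "singular_values", np.asarray(self.singular_values, dtype=float)
        )
        s = self.singular_values
        if s.ndim != 1 or self.factors.shape[1] != s.shape[0]:
            raise ValueError("factor columns must match the retained spectrum")
        if s.size and (np.any(s < 0) or np.any(np.diff(s) > 1e-12)):
            raise ValueError("singular values must be non-negative, non-increasing")

    @property
    def rank(self) -> int:
        return self.factors.shape[1]

    def project(self, sim_rows: np.ndarray) -> np.ndarray:
        """Nystrom out-of-sample projection of similarity rows.

        With factors F = U sqrt(s), a new entity's latent row is
        s_x U s^(-1/2) = s_x F / s; components with zero singular value are
        mapped to zero.
        """
        rows = np.atleast_2d(np.asarray(sim_rows, dtype=float))
        if rows.shape[1] != self.factors.shape[0]:
            raise ValueError(
                f"similarity rows of length {rows.shape[1]} do not match "
                f"{self.factors.shape[0]} training entities"
            )
        inv = np.zeros_like(self.singular_values)
        pos = self.singular_values > _RANK_TOL
        inv[pos] = 1.0 / self.singular_values[pos]
        return rows @ self.factors * inv


def _fix_signs(u: np.ndarray, *others: np.ndarray) -> None:
    """Force the largest-magnitude entry of each U column non-negative (in place)."""
    for j in range(u.shape[1]):
        col = u[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            u[:, j] = -col
            for o in others:
                o[:, j] = -o[:, j]


def _auto_rank(spectrum: np.ndarray) -> int:
    smax = spectrum[0] if spectrum.size else 0.0
    if smax <= 0:
        return 1
    return int(np.sum(spectrum > _RANK_TOL * smax))


def svd_embed(
    m: np.ndarray,
    rank: int,
    row_ids: tuple[str, ...] | None = None,
    col_ids: tuple[str, ...] | None = None,
) -> tuple[Embedding, Embedding]:
    """Rank-truncated SVD factorization M ~ L R' with L = U sqrt(S), R = V sqrt(S)."""
    m = np.asarray(m, dtype=float)
    if not 1 <= rank <= min(m.shape):
        raise ValueError(f"rank {rank} out of range for shape {m.shape}")
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    v = vt.T
    _fix_signs(u, v)
    u, s, v = u[:, :rank], s[:rank], v[:, :rank]
    root = np.sqrt(s)
    row_ids = row_ids or tuple(str(i) for i in range(m.shape[0]))
    col_ids = col_ids or tuple(str(i) for i in range(m.shape[1]))
    return Embedding(row_ids, u * root, s), Embedding(col_ids, v * root, s)


def symmetric_embed(
    s_mat: SimilarityMatrix | np.ndarray,
    rank: int | None = None,
    ids: tuple[str, ...] | None = None,
) -> Embedding:
    """Eigen-embedding F = U sqrt(L+) of a symmetric similarity matrix.

    Similarities of the 1/(1+dist) form are not guaranteed positive
    semidefinite; negative eigenvalues are clipped to zero so the square root
    stays real and F F' reconstructs the PSD part of S.
    """
    if isinstance(s_mat, SimilarityMatrix):
        ids, values = s_mat.ids, s_mat.values
    else:
        values = np.asarray(s_mat, dtype=float)
        ids = ids or tuple(str(i) for i in range(values.shape[0]))
    if values.shape[0] != values.shape[1] or (
        values.size and np.max(np.abs(values - values.T)) > _SYM_TOL
    ):
        raise ValueError("symmetric_embed requires a symmetric matrix")
    w, u = np.linalg.eigh(values)
    order = np.argsort(w)[::-1]
    w, u = np.clip(w[order], 0.0, None), u[:, order].copy()
    _fix_signs(u)
    if rank is None:
        rank = _auto_rank(w)
    if not 1 <= rank <= values.shape[0]:
        raise ValueError(f"rank {rank} out of range for shape {values.shape}")
    w, u = w[:rank], u[:, :rank]
    return Embedding(ids, u * np.sqrt(w), w)


def pls_regress(
    x: np.ndarray, y: np.ndarray, n_components: int, ridge: float = 0.0
) -> np.ndarray:
    """Uncentered multi-response PLS (PLS2) coefficient matrix B: x @ B ~ y.

    Components are extracted from the raw cross-covariance without centering
    or scaling, as required by the intercept-free bilinear predictors.  Each
    weight vector is the dominant left singular vector of X_k' Y_k (the fixed
    point of the NIPALS inner loop); X is deflated by the score direction.
    With ``n_components >= rank(X)`` and an exact linear relation Y = X B,
    the relation is recovered exactly.  ``ridge > 0`` shrinks the final
    regression of Y on the latent scores.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError(f"incompatible shapes {x.shape} / {y.shape}")
    n, p = x.shape
    r = y.shape[1]
    if not np.any(x):
        raise ValueError("degenerate predictor matrix: all zeros")
    if not 1 <= n_components <= min(n, p):
        raise ValueError(f"n_components {n_components} out of range for {x.shape}")
    if r == 0 or not np.any(y):
        return np.zeros((p, r))
    tol = 1e-12 * max(np.abs(x).max(), 1.0) * max(np.abs(y).max(), 1.0)
    xk, yk = x.copy(), y.copy()
    weights, loadings = [], []
    for _ in range(n_components):
        cov = xk.T @ yk
        if np.linalg.norm(cov) <= tol:
            break
        u, _, _ = np.linalg.svd(cov, full_matrices=False)
        w = u[:, 0]
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        t = xk @ w
        tt = float(t @ t)
        if tt <= tol**2 or tt <= 1e-300:
            break
        p_load = xk.T @ t / tt
        c_load = yk.T @ t / tt
        xk = xk - np.outer(t, p_load)
        yk = yk - np.outer(t, c_load)
        weights.append(w)
        loadings.append(p_load)
    if not weights:
        return np.zeros((p, r))
    w_mat = np.column_stack(weights)
    p_mat = np.column_stack(loadings)
    # rotation from X to scores: T = X R
    rot = w_mat @ np.linalg.solve(p_mat.T @ w_mat, np.eye(w_mat.shape[1]))
    t_mat = x @ rot
    gram = t_mat.T @ t_mat + ridge * np.eye(t_mat.shape[1])
    return rot @ np.linalg.solve(gram, t_mat.T @ y)


def project_similarity_rows(sim_rows: np.ndarray, embedding: Embedding) -> np.ndarray:
    """Latent rows for new entities from their similarity to training entities."""
    return embedding.project(sim_rows)


def _coerce_assoc(a) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    if isinstance(a, LdaMatrix):
        return a.values, a.lncrna_ids, a.disease_ids
    arr = np.asarray(a, dtype=float)
    return (
        arr,
        tuple(str(i) for i in range(arr.shape[0])),
        tuple(str(i) for i in range(arr.shape[1])),
    )


def _coerce_sim(s, n: int, ids: tuple[str, ...], what: str):
    if isinstance(s, SimilarityMatrix):
        if s.n != n:
            raise ValueError(
                f"{what} similarity has {s.n} entities, association has {n}"
            )
        return s.values, s.ids
    arr = np.asarray(s, dtype=float)
    if arr.shape != (n, n):
        raise ValueError(f"{what} similarity shape {arr.shape} != ({n}, {n})")
    return arr, ids


class GrufRegressor(BaseEstimator):
    """Graph-regression predictor of lncRNA-disease association scores.

    Parameters
    ----------
    rank_assoc, rank_lncrna, rank_disease : int or None
        Latent dimensions r, p, q of the association SVD and the two
        similarity eigen-embeddings.  ``None`` keeps the full numerically
        non-zero spectrum (relative tolerance 1e-10).
    n_components : int or None
        PLS components for both regressions; ``None`` uses min(p, r) and
        min(q, r), clipped to the sample counts.
    ridge : float
        Optional shrinkage of the regression of the associating factors on
        the latent scores (0 = plain PLS).

    Attributes (after :meth:`fit`)
    ------------------------------
    ra_, da_ : Embedding      associating factors A_r, A_d
    fr_, fd_ : Embedding      latent feature factors F_r, F_d
    br_, bd_ : ndarray        regression coefficients B_r (p x r), B_d (q x r)
    theta_ : ndarray          bi-regression matrix B_r B_d' (p x q)
    ranks_ : tuple            realized (r, p, q)
    """

    def __init__(
        self,
        rank_assoc: int | None = None,
        rank_lncrna: int | None = None,
        rank_disease: int | None = None,
        n_components: int | None = None,
        ridge: float = 0.0,
    ):
        self.rank_assoc = rank_assoc
        self.rank_lncrna = rank_lncrna
        self.rank_disease = rank_disease
        self.n_components = n_components
        self.ridge = ridge

    def fit(self, A, S_r, S_d, y=None):
        values, lnc_ids, dis_ids = _coerce_assoc(A)
        sr, sr_ids = _coerce_sim(S_r, values.shape[0], lnc_ids, "lncRNA")
        sd, sd_ids = _coerce_sim(S_d, values.shape[1], dis_ids, "disease")
        if sr_ids != lnc_ids:
            off = [i for i, (a, b) in enumerate(zip(sr_ids, lnc_ids)) if a != b]
            raise ValueError(
                f"lncRNA ids of similarity and association differ at positions {off[:10]}"
            )
        if sd_ids != dis_ids:
            off = [i for i, (a, b) in enumerate(zip(sd_ids, dis_ids)) if a != b]
            raise ValueError(
                f"disease ids of similarity and association differ at positions {off[:10]}"
            )

        spectrum = np.linalg.svd(values, compute_uv=False)
        r = self.rank_assoc if self.rank_assoc is not None else _auto_rank(spectrum)
        self.ra_, self.da_ = svd_embed(values, r, lnc_ids, dis_ids)

        self.fr_ = symmetric_embed(sr, self.rank_lncrna, ids=lnc_ids)
        self.fd_ = symmetric_embed(sd, self.rank_disease, ids=sd_ids)
        p, q = self.fr_.rank, self.fd_.rank

        nc_r = self.n_components or min(p, r)
        nc_d = self.n_components or min(q, r)
        nc_r = min(nc_r, values.shape[0], p)
        nc_d = min(nc_d, values.shape[1], q)
        self.br_ = pls_regress(self.fr_.factors, self.ra_.factors, nc_r, self.ridge)
        self.bd_ = pls_regress(self.fd_.factors, self.da_.factors, nc_d, self.ridge)
        self.theta_ = self.br_ @ self.bd_.T
        self.ranks_ = (r, p, q)
        self.lncrna_ids_ = lnc_ids
        self.disease_ids_ = dis_ids
        return self

    def _check_fitted(self):
        if not hasattr(self, "theta_"):
            raise AttributeError("model is not fitted; call fit() first")

    def predict(self, task: str = "T1", s_new_lncrna=None, s_new_disease=None) -> ScoreMatrix:
        """Confidence scores for one of the four prediction scenarios.

        T2/T4 require ``s_new_lncrna`` (rows of similarities to the training
        lncRNAs); T3/T4 require ``s_new_disease`` analogously.
        """
        self._check_fitted()
        task = task.upper()
        if task not in ("T1", "T2", "T3", "T4"):
            raise ValueError(f"unknown task {task!r}")
        if task in ("T2", "T4"):
            if s_new_lncrna is None:
                raise ValueError(f"{task} requires similarity rows for new lncRNAs")
            fr = self.fr_.project(s_new_lncrna)
            row_ids = tuple(f"new_lncrna_{i}" for i in range(fr.shape[0]))
        else:
            fr, row_ids = self.fr_.factors, self.lncrna_ids_
        if task in ("T3", "T4"):
            if s_new_disease is None:
                raise ValueError(f"{task} requires similarity rows for new diseases")
            fd = self.fd_.project(s_new_disease)
            col_ids = tuple(f"new_disease_{i}" for i in range(fd.shape[0]))
        else:
            fd, col_ids = self.fd_.factors, self.disease_ids_
        return ScoreMatrix(row_ids, col_ids, fr @ self.theta_ @ fd.T)

    # convenience wrappers mirroring the four scenarios
    def predict_T1(self) -> ScoreMatrix:
        return self.predict("T1")

    def predict_T2(self, s_new_lncrna) -> ScoreMatrix:
        return self.predict("T2", s_new_lncrna=s_new_lncrna)

    def predict_T3(self, s_new_disease) -> ScoreMatrix:
        return self.predict("T3", s_new_disease=s_new_disease)

    def predict_T4(self, s_new_lncrna, s_new_disease) -> ScoreMatrix:
        return self.predict(
            "T4", s_new_lncrna=s_new_lncrna, s_new_disease=s_new_disease
        )


def fit(
    A,
    S_r,
    S_d,
    ranks: tuple[int | None, int | None, int | None] = (None, None, None),
    n_components: int | None = None,
    ridge: float = 0.0,
) -> GrufRegressor:
    """Functional wrapper over :class:`GrufRegressor`."""
    r, p, q = ranks
    return GrufRegressor(
        rank_assoc=r,
        rank_lncrna=p,
        rank_disease=q,
        n_components=n_components,
        ridge=ridge,
    ).fit(A, S_r, S_d)
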