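"""Reverse kernel ridge regression: fingerprint feature space into spectrum
feature space, with the pre-image solved in the *input* space.

Motivated by hubness in high-dimensional nearest-neighbour retrieval, the
regression is reversed: g minimizing sum_i ||g(y_i) - phi(x_i)||^2
+ lambda ||g||^2 has the representer form g(y) = sum_i beta_i(y) phi(x_i)
with

    beta(y) = (lambda I + K_Y)^{-1} k_Y^y.

Each candidate y of a query spectrum x is ranked by

    d^2(y) = beta(y)^T K_X beta(y) + k_x(x, x) - 2 beta(y)^T k_X^x,

i.e. the distance between the candidate's predicted spectrum embedding and
the observed one. Per-query work grows with the candidate count (one
coefficient column per candidate), which is why this direction is the
heavier one at prediction time; candidates recur across queries, so betas
for the union of a fold's candidates are computed once in a single
multi-right-hand-side solve and reused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import KernelMatrix
from .forward import _spd_factor

logger = logging.getLogger("iokr")

__all__ = [
    "ReverseModel",
    "fit_reverse",
    "beta",
    "reverse_sq_distances",
    "reverse_cosine_scores",
    "tune_lambda_by_mse_reverse",
]


@dataclass
class ReverseModel:
    """Fitted reverse regressor: factorization of (lambda I + K_Y) plus the
    training input Gram matrix, both in training order."""

    train_ids: list[str]
    lambda_g: float
    _factor: tuple
    K_X_train: np.ndarray

    @property
    def n_train(self) -> int:
        return len(self.train_ids)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        from scipy.linalg import cho_solve

        return cho_solve(self._factor, rhs)


def fit_reverse(K_Y: KernelMatrix, K_X: KernelMatrix, lambda_g: float) -> ReverseModel:
    """Fit the fingerprint-to-spectrum ridge regression (roles of the two
    Gram matrices swapped relative to the forward direction)."""
    if lambda_g <= 0:
        raise ValueError("lambda_g must be > 0")
    if not K_X.is_square or not K_Y.is_square:
        raise ValueError("training kernel matrices must be square")
    if K_X.row_ids != K_Y.row_ids:
        raise ValueError("K_X and K_Y must share the same training order")
    ell = len(K_Y.row_ids)
    factor = _spd_factor(lambda_g * np.eye(ell) + K_Y.values)
    return ReverseModel(list(K_Y.row_ids), lambda_g, factor, K_X.values.copy())


def beta(model: ReverseModel, k_Y_cand: np.ndarray) -> np.ndarray:
    """Coefficient matrix B with column j = beta(y_j) for candidate j.

    ``k_Y_cand`` is the (ell, n_c) train-by-candidate output cross kernel;
    all candidates are solved in one multi-RHS solve.
    """
    k = np.asarray(k_Y_cand, dtype=float)
    if k.shape[0] != model.n_train:
        raise ValueError(
            f"candidate kernel matrix has {k.shape[0]} rows, expected {model.n_train}"
        )
    return model.solve(k)


def reverse_sq_distances(
    B: np.ndarray,
    model: ReverseModel,
    k_X_query: np.ndarray,
    k_xx: float,
) -> np.ndarray:
    """Squared input-feature-space distances ||g(y) - phi(x)||^2 per candidate.

    ``k_X_query`` is the query's length-ell input kernel vector against the
    training spectra and ``k_xx`` its preprocessed self-kernel (1 when
    cosine-normalized). Round-off negatives are clipped to 0.
    """
    B = np.asarray(B, dtype=float)
    k_x = np.asarray(k_X_query, dtype=float)
    if B.shape[0] != model.n_train or k_x.shape[0] != model.n_train:
        raise ValueError("alignment mismatch between beta, model and query")
    M = model.K_X_train @ B
    quad = np.einsum("ij,ij->j", B, M)
    d2 = quad + float(k_xx) - 2.0 * (B.T @ k_x)
    neg = d2 < 0
    if neg.any():
        logger.debug("clipping %d slightly negative squared distances", neg.sum())
        d2 = np.where(neg, 0.0, d2)
    return d2


def reverse_cosine_scores(
    B: np.ndarray,
    model: ReverseModel,
    k_X_query: np.ndarray,
    k_xx: float,
) -> np.ndarray:
    """Cosine similarity between each candidate's predicted spectrum
    embedding g(y) and the observed phi(x):
    beta^T k_X^x / (sqrt(beta^T K_X beta) sqrt(k_x(x, x))).

    Candidates with degenerate ||g(y)|| get score 0 with a warning.
    """
    B = np.asarray(B, dtype=float)
    k_x = np.asarray(k_X_query, dtype=float)
    M = model.K_X_train @ B
    quad = np.einsum("ij,ij->j", B, M)
    cross = B.T @ k_x
    if k_xx <= 1e-12:
        logger.warning("degenerate query self-kernel; cosine scores set to 0")
        return np.zeros_like(cross)
    ok = quad > 1e-12
    if not ok.all():
        logger.warning(
            "%d candidate(s) with degenerate predicted-embedding norm scored 0",
            int((~ok).sum()),
        )
    scores = np.zeros_like(cross)
    scores[ok] = cross[ok] / (np.sqrt(quad[ok]) * np.sqrt(k_xx))
    return scores


def tune_lambda_by_mse_reverse(
    K_Y: KernelMatrix,
    K_X: KernelMatrix,
    grid,
    n_inner_folds: int = 4,
    seed: int = 0,
) -> float:
    """Inner-CV MSE selection of lambda_g: the forward tuner with the roles
    of the input and output Gram matrices swapped (held-out error measured
    in the input feature space)."""
    from .forward import tune_lambda_by_mse

    return tune_lambda_by_mse(K_Y, K_X, grid, n_inner_folds=n_inner_folds, seed=seed)
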