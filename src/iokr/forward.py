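"""Kernel ridge regression from spectrum feature space into fingerprint
feature space (the IOKR direction), with kernelized pre-image distances and
cosine compatibility scores over candidate molecule sets.

The regression h minimizing sum_i ||h(x_i) - psi(y_i)||^2 + lambda ||h||^2
has the representer form h(x) = sum_i alpha_i(x) psi(y_i) with

    alpha(x) = (lambda I + K_X)^{-1} k_X^x.

Identification ranks the candidates y of a query x by the feature-space
squared distance

    d^2(y) = alpha^T K_Y alpha + k_y(y, y) - 2 alpha^T k_Y^y

or, for score fusion, by the cosine similarity between h(x) and psi(y).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .data import KernelMatrix

logger = logging.getLogger("iokr")

__all__ = [
    "IOKRModel",
    "fit_iokr",
    "alpha",
    "candidate_sq_distances",
    "cosine_scores",
    "tune_lambda_by_mse",
]


def _spd_factor(A: np.ndarray):
    """Cholesky of a (nearly) SPD matrix; one jitter retry, then fail."""
    try:
        return cho_factor(A, lower=True)
    except LinAlgError:
        jitter = 1e-10 * np.trace(A) / A.shape[0]
        logger.debug("Cholesky failed; retrying with jitter %g", jitter)
        return cho_factor(A + jitter * np.eye(A.shape[0]), lower=True)


@dataclass
class IOKRModel:
    """Fitted IOKR regressor: a factorization of (lambda I + K_X) plus the
    training output Gram matrix, both in training order."""

    train_ids: list[str]
    lambda_h: float
    _factor: tuple
    K_Y_train: np.ndarray

    @property
    def n_train(self) -> int:
        return len(self.train_ids)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Apply (lambda I + K_X)^{-1} to one or many right-hand sides."""
        return cho_solve(self._factor, rhs)


def fit_iokr(K_X: KernelMatrix, K_Y: KernelMatrix, lambda_h: float) -> IOKRModel:
    """Fit the spectrum-to-fingerprint ridge regression.

    Both Gram matrices must be square and aligned to the same training order;
    they are expected to be preprocessed consistently (typically centered and
    cosine-normalized). Fitting cost is independent of any candidate set.
    """
    if lambda_h <= 0:
        raise ValueError("lambda_h must be > 0")
    if not K_X.is_square or not K_Y.is_square:
        raise ValueError("training kernel matrices must be square")
    if K_X.row_ids != K_Y.row_ids:
        raise ValueError("K_X and K_Y must share the same training order")
    ell = len(K_X.row_ids)
    factor = _spd_factor(lambda_h * np.eye(ell) + K_X.values)
    return IOKRModel(list(K_X.row_ids), lambda_h, factor, K_Y.values.copy())


def alpha(model: IOKRModel, k_x_query: np.ndarray) -> np.ndarray:
    """Representer coefficients alpha(x) = (lambda I + K_X)^{-1} k_X^x.

    ``k_x_query`` may be a length-ell vector (one query) or an (ell, n_q)
    matrix (one column per query; a single multi-RHS solve).
    """
    k = np.asarray(k_x_query, dtype=float)
    if k.shape[0] != model.n_train:
        raise ValueError(
            f"query kernel vector has length {k.shape[0]}, expected {model.n_train}"
        )
    return model.solve(k)


def candidate_sq_distances(
    a: np.ndarray,
    model: IOKRModel,
    k_Y_cand: np.ndarray,
    cand_self: np.ndarray,
) -> np.ndarray:
    """Squared feature-space distances from h(x) to every candidate.

    ``k_Y_cand`` is the (ell, n_c) train-by-candidate output cross kernel and
    ``cand_self`` the candidates' self-kernels k_y(y, y) (all 1 after cosine
    normalization), preprocessed consistently with the training Gram.
    Slightly negative values from round-off are clipped to 0.
    """
    a = np.asarray(a, dtype=float)
    k_Y_cand = np.asarray(k_Y_cand, dtype=float)
    if k_Y_cand.shape[0] != model.n_train or a.shape[0] != model.n_train:
        raise ValueError("alignment mismatch between alpha, model and candidates")
    quad = float(a @ model.K_Y_train @ a)
    d2 = quad + np.asarray(cand_self, dtype=float) - 2.0 * (a @ k_Y_cand)
    neg = d2 < 0
    if neg.any():
        logger.debug("clipping %d slightly negative squared distances", neg.sum())
        d2 = np.where(neg, 0.0, d2)
    return d2


def cosine_scores(
    a: np.ndarray,
    model: IOKRModel,
    k_Y_cand: np.ndarray,
    cand_self: np.ndarray,
) -> np.ndarray:
    """Cosine similarity between the prediction h(x) and each candidate:
    alpha^T k_Y^y / (sqrt(alpha^T K_Y alpha) sqrt(k_y(y, y))).

    A degenerate prediction norm (alpha^T K_Y alpha <= 1e-12) yields all-zero
    scores with a logged warning; a degenerate candidate self-kernel yields a
    zero score for that candidate.
    """
    a = np.asarray(a, dtype=float)
    quad = float(a @ model.K_Y_train @ a)
    cand_self = np.asarray(cand_self, dtype=float)
    cross = a @ np.asarray(k_Y_cand, dtype=float)
    if quad <= 1e-12:
        logger.warning("degenerate prediction norm; cosine scores set to 0")
        return np.zeros_like(cross)
    ok = cand_self > 1e-12
    scores = np.zeros_like(cross)
    scores[ok] = cross[ok] / (np.sqrt(quad) * np.sqrt(cand_self[ok]))
    return scores


def tune_lambda_by_mse(
    K_X: KernelMatrix,
    K_Y: KernelMatrix,
    grid,
    n_inner_folds: int = 4,
    seed: int = 0,
) -> float:
    """Select the ridge parameter by inner-CV mean squared error.

    The held-out error of a point (x_i, y_i) is evaluated entirely with the
    kernel trick: ||h(x_i) - psi(y_i)||^2 = alpha^T K_Y alpha
    - 2 alpha^T k_Y^{y_i} + k_y(y_i, y_i). Ties break to the larger lambda.
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("lambda grid must be nonempty")
    if any(g <= 0 for g in grid):
        raise ValueError("all lambda values must be > 0")
    ell = len(K_X.row_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ell)
    folds = np.array_split(perm, n_inner_folds)
    KX, KY = K_X.values, K_Y.values

    best_lam, best_mse = None, np.inf
    for lam in sorted(grid):
        errs = []
        for fold in folds:
            if fold.size == 0 or fold.size == ell:
                continue
            tr = np.setdiff1d(perm, fold, assume_unique=True)
            factor = _spd_factor(lam * np.eye(tr.size) + KX[np.ix_(tr, tr)])
            A = cho_solve(factor, KX[np.ix_(tr, fold)])  # (n_tr, n_te) alphas
            KY_tt = KY[np.ix_(tr, tr)]
            quad = np.einsum("ij,ik,kj->j", A, KY_tt, A)
            cross = np.einsum("ij,ij->j", A, KY[np.ix_(tr, fold)])
            self_y = np.diag(KY)[fold]
            errs.extend(quad - 2.0 * cross + self_y)
        mse = float(np.mean(errs))
        if mse <= best_mse:  # <= so ties promote the larger lambda
            best_mse = mse
            best_lam = lam
    return best_lam  # type: ignore[return-value]
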