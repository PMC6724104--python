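"""Input kernels on spectra, output kernels on fingerprints, and Gram-matrix
preprocessing (feature-space centering, cosine normalization, uniform
multiple-kernel combination, entropy-based bandwidth selection).

The probability product kernel (PPK) treats each peak of an MS/MS spectrum as
a 2-D Gaussian in (m/z, intensity) with standard deviations ``sigma_m`` and
``sigma_i`` and integrates the product of the two spectrum densities:

    k(x, x') = 1/(n_x n_x') * 1/(4 pi sigma_m sigma_i)
               * sum_{l, l'} exp(-(m_l - m'_l')^2 / (4 sigma_m^2))
                            * exp(-(i_l - i'_l')^2 / (4 sigma_i^2))

Output kernels compare binary molecular fingerprints: linear (shared-bit
count), Tanimoto (Jaccard on bit sets), Gaussian on the raw bit vectors and
Gaussian on the Tanimoto feature-space distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import FingerprintTable, KernelMatrix, Spectrum

logger = logging.getLogger("iokr")

__all__ = [
    "PPKParams",
    "GaussianParams",
    "ppk",
    "ppk_matrix",
    "linear_fp_kernel",
    "tanimoto_kernel",
    "gaussian_fp_kernel",
    "gaussian_tanimoto_kernel",
    "center_train",
    "center_cross",
    "normalize",
    "unimkl_combine",
    "select_gamma_by_entropy",
    "TrainKernelStats",
    "preprocess_train",
    "preprocess_cross",
]


@dataclass(frozen=True)
class PPKParams:
    """Peak-shape standard deviations of the probability product kernel."""

    sigma_m: float  # mass std-dev, Daltons
    sigma_i: float  # intensity std-dev, intensity units

    def __post_init__(self) -> None:
        if self.sigma_m <= 0 or self.sigma_i <= 0:
            raise ValueError("PPK standard deviations must be strictly positive")


@dataclass(frozen=True)
class GaussianParams:
    """Inverse squared bandwidth of the Gaussian output kernels."""

    gamma: float

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


# ---------------------------------------------------------------------------
# Input kernel: probability product kernel


def _ppk_intensities(s: Spectrum, rescale: bool) -> np.ndarray:
    if not rescale:
        return s.intensity
    peak = s.intensity.max()
    return s.intensity / peak if peak > 0 else s.intensity


def ppk(a: Spectrum, b: Spectrum, p: PPKParams, *, rescale_intensity: bool = True) -> float:
    """Probability product kernel between two spectra.

    Intensities are scaled to max 1 per spectrum before evaluation unless
    ``rescale_intensity`` is disabled.
    """
    ia = _ppk_intensities(a, rescale_intensity)
    ib = _ppk_intensities(b, rescale_intensity)
    dm = a.mz[:, None] - b.mz[None, :]
    di = ia[:, None] - ib[None, :]
    terms = np.exp(-(dm**2) / (4.0 * p.sigma_m**2) - (di**2) / (4.0 * p.sigma_i**2))
    scale = 1.0 / (a.n_peaks * b.n_peaks * 4.0 * np.pi * p.sigma_m * p.sigma_i)
    return float(scale * terms.sum())


def ppk_matrix(
    rows: Sequence[Spectrum],
    cols: Sequence[Spectrum],
    p: PPKParams,
    *,
    rescale_intensity: bool = True,
) -> KernelMatrix:
    """Pairwise PPK Gram (square) or cross (rectangular) matrix."""
    if not rows or not cols:
        raise ValueError("spectrum lists must be nonempty")
    square = [s.id for s in rows] == [s.id for s in cols]
    values = np.empty((len(rows), len(cols)))
    for i, a in enumerate(rows):
        j0 = i if square else 0
        for j in range(j0, len(cols)):
            values[i, j] = ppk(a, cols[j], p, rescale_intensity=rescale_intensity)
            if square:
                values[j, i] = values[i, j]
    return KernelMatrix([s.id for s in rows], [s.id for s in cols], values)


# ---------------------------------------------------------------------------
# Output kernels on fingerprints


def _fp_matrices(
    fps: FingerprintTable, row_ids: Sequence[str], col_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    return fps.matrix(row_ids), fps.matrix(col_ids)


def linear_fp_kernel(
    fps: FingerprintTable, row_ids: Sequence[str], col_ids: Sequence[str]
) -> KernelMatrix:
    """k(y, y') = fp(y)^T fp(y'): count of shared active bits."""
    A, B = _fp_matrices(fps, row_ids, col_ids)
    return KernelMatrix(list(row_ids), list(col_ids), A @ B.T)


def _tanimoto_values(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    inter = A @ B.T
    na = A.sum(axis=1)[:, None]
    nb = B.sum(axis=1)[None, :]
    union = na + nb - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    return vals


def tanimoto_kernel(
    fps: FingerprintTable, row_ids: Sequence[str], col_ids: Sequence[str]
) -> KernelMatrix:
    """Tanimoto (Jaccard) kernel on binary fingerprints; values in [0, 1].

    The 0/0 case of two all-zero fingerprints is defined as 1 (identical
    empty bit sets) and logged once.
    """
    A, B = _fp_matrices(fps, row_ids, col_ids)
    if (A.sum(axis=1) == 0).any() or (B.sum(axis=1) == 0).any():
        logger.warning("all-zero fingerprint(s); Tanimoto 0/0 defined as 1")
    return KernelMatrix(list(row_ids), list(col_ids), _tanimoto_values(A, B))


def gaussian_fp_kernel(
    fps: FingerprintTable,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    g: GaussianParams,
) -> KernelMatrix:
    """k(y, y') = exp(-gamma * ||fp(y) - fp(y')||^2).

    For binary vectors the squared distance equals the Hamming bit count.
    """
    A, B = _fp_matrices(fps, row_ids, col_ids)
    sq = (A**2).sum(1)[:, None] + (B**2).sum(1)[None, :] - 2.0 * (A @ B.T)
    return KernelMatrix(list(row_ids), list(col_ids), np.exp(-g.gamma * np.maximum(sq, 0.0)))


def gaussian_tanimoto_kernel(
    fps: FingerprintTable,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    g: GaussianParams,
) -> KernelMatrix:
    """Gaussian kernel on the Tanimoto feature-space distance:
    exp(-gamma * (k_tan(y,y) + k_tan(y',y') - 2 k_tan(y,y'))).
    """
    A, B = _fp_matrices(fps, row_ids, col_ids)
    ktan = _tanimoto_values(A, B)
    # k_tan(y, y) = 1 for any fingerprint (including the all-zero convention)
    sq = np.maximum(2.0 - 2.0 * ktan, 0.0)
    return KernelMatrix(list(row_ids), list(col_ids), np.exp(-g.gamma * sq))


# ---------------------------------------------------------------------------
# Centering & normalization in feature space


def center_train(K: KernelMatrix) -> KernelMatrix:
    """Center a square training Gram matrix in feature space.

    Row/column sums of the result vanish. The raw diagonal is retained in
    ``row_self``/``col_self`` of the *input* semantics via the returned
    matrix's centered diagonal; use :func:`center_cross` for test rows.
    """
    if not K.is_square:
        raise ValueError("center_train requires a square kernel matrix")
    if K.centered:
        raise ValueError("kernel matrix already centered (double centering refused)")
    V = K.values
    row_means = V.mean(axis=1, keepdims=True)
    col_means = V.mean(axis=0, keepdims=True)
    grand = V.mean()
    Vc = V - row_means - col_means + grand
    Vc = 0.5 * (Vc + Vc.T)  # restore exact symmetry against round-off
    return KernelMatrix(
        list(K.row_ids),
        list(K.col_ids),
        Vc,
        centered=True,
        normalized=False,
        row_self=np.diag(V).copy(),
        col_self=np.diag(V).copy(),
    )


def center_cross(K_tx: KernelMatrix, K_train_raw: KernelMatrix) -> KernelMatrix:
    """Center a test-by-train cross matrix with *training* statistics only.

    k_c(x, x_j) = k(x, x_j) - mean_j' k(x, x_j') - mean_i k(x_i, x_j)
                  + grandmean(K_train).

    If ``K_tx.row_self`` carries the raw self-kernels k(x, x) of the test
    points, the output's ``row_self`` holds their centered values
    k_c(x, x) = k(x,x) - 2 mean_j k(x, x_j) + grandmean, which cosine
    normalization of the rows needs.
    """
    if not K_train_raw.is_square:
        raise ValueError("training kernel must be square")
    if K_train_raw.centered:
        raise ValueError("training kernel must be raw (uncentered)")
    if K_tx.col_ids != K_train_raw.col_ids:
        raise ValueError("cross-matrix columns misaligned with training ids")
    V = K_tx.values
    T = K_train_raw.values
    test_means = V.mean(axis=1, keepdims=True)
    train_col_means = T.mean(axis=0, keepdims=True)
    grand = T.mean()
    Vc = V - test_means - train_col_means + grand
    row_self_c = None
    if K_tx.row_self is not None:
        row_self_c = (
            np.asarray(K_tx.row_self, dtype=float) - 2.0 * test_means.ravel() + grand
        )
    train_diag_c = np.diag(T) - T.mean(axis=1) - train_col_means.ravel() + grand
    return KernelMatrix(
        list(K_tx.row_ids),
        list(K_tx.col_ids),
        Vc,
        centered=True,
        normalized=False,
        row_self=row_self_c,
        col_self=train_diag_c,
    )


def normalize(
    K: KernelMatrix,
    row_self: np.ndarray | None = None,
    col_self: np.ndarray | None = None,
) -> KernelMatrix:
    """Cosine-normalize: k / sqrt(k(x,x) k(x',x')).

    Self values default to the matrix's stored ``row_self``/``col_self`` or,
    for a raw square matrix, its diagonal. Degenerate self values (<= 1e-12)
    raise, naming the offending id.
    """
    if row_self is None:
        row_self = K.row_self if K.row_self is not None else (
            np.diag(K.values).copy() if K.is_square else None
        )
    if col_self is None:
        col_self = K.col_self if K.col_self is not None else (
            np.diag(K.values).copy() if K.is_square else None
        )
    if row_self is None or col_self is None:
        raise ValueError("self-kernel values required to normalize a cross matrix")
    row_self = np.asarray(row_self, dtype=float)
    col_self = np.asarray(col_self, dtype=float)
    for ids, selfs in ((K.row_ids, row_self), (K.col_ids, col_self)):
        bad = np.nonzero(selfs <= 1e-12)[0]
        if bad.size:
            raise ValueError(
                f"degenerate self-kernel (<= 1e-12) for id {ids[bad[0]]!r}"
            )
    Vn = K.values / np.sqrt(row_self[:, None] * col_self[None, :])
    if K.is_square:
        np.fill_diagonal(Vn, 1.0)
        Vn = 0.5 * (Vn + Vn.T)
    return KernelMatrix(
        list(K.row_ids),
        list(K.col_ids),
        Vn,
        centered=K.centered,
        normalized=True,
        row_self=np.ones_like(row_self),
        col_self=np.ones_like(col_self),
    )


def unimkl_combine(Ks: Sequence[KernelMatrix]) -> KernelMatrix:
    """Uniform multiple-kernel combination: entrywise mean of the inputs.

    All inputs must be centered+normalized square matrices on identical ids.
    The mean of normalized kernels is not unit-diagonal, so the result carries
    centered=True, normalized=False; callers re-normalize.
    """
    if not Ks:
        raise ValueError("unimkl_combine requires at least one kernel")
    first = Ks[0]
    for K in Ks:
        if K.row_ids != first.row_ids or K.col_ids != first.col_ids:
            raise ValueError("unimkl_combine: id mismatch across kernels")
        if not (K.centered and K.normalized):
            raise ValueError("unimkl_combine expects centered+normalized kernels")
    mean = np.mean([K.values for K in Ks], axis=0)
    return KernelMatrix(
        list(first.row_ids), list(first.col_ids), mean,
        centered=True, normalized=False,
        row_self=np.diag(mean).copy(), col_self=np.diag(mean).copy(),
    )


# ---------------------------------------------------------------------------
# Entropy-based gamma selection


def select_gamma_by_entropy(
    sq_distances: np.ndarray, grid: Sequence[float], n_bins: int = 100
) -> GaussianParams:
    """Pick gamma maximizing the Shannon entropy of binned kernel values.

    For each candidate gamma the off-diagonal kernel values
    exp(-gamma * d^2) are binned into ``n_bins`` equal-width bins on [0, 1]
    and the entropy of the bin distribution is computed; ties break to the
    smaller gamma.
    """
    if len(grid) == 0:
        raise ValueError("gamma grid must be nonempty")
    d2 = np.asarray(sq_distances, dtype=float).ravel()
    if d2.size == 0 or np.all(d2 == 0):
        raise ValueError("degenerate dataset: all pairwise distances are zero")
    best_gamma = None
    best_h = -np.inf
    for g in sorted(float(x) for x in grid):
        vals = np.exp(-g * d2)
        counts, _ = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
        p = counts[counts > 0] / counts.sum()
        h = float(-(p * np.log(p)).sum())
        if h > best_h:  # strict: ties keep the smaller gamma
            best_h = h
            best_gamma = g
    return GaussianParams(best_gamma)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Convenience pipeline: train statistics + matched cross preprocessing


@dataclass
class TrainKernelStats:
    """Raw training Gram plus its centered+normalized form, for reuse on
    test-by-train cross matrices."""

    raw: KernelMatrix
    processed: KernelMatrix
    centered_diag: np.ndarray


def preprocess_train(K_raw: KernelMatrix) -> TrainKernelStats:
    """Center then cosine-normalize a raw training Gram matrix."""
    Kc = center_train(K_raw)
    diag = np.diag(Kc.values).copy()
    Kn = normalize(Kc, diag, diag)
    return TrainKernelStats(raw=K_raw, processed=Kn, centered_diag=diag)


def preprocess_cross(
    K_tx_raw: KernelMatrix, row_self_raw: np.ndarray, stats: TrainKernelStats
) -> KernelMatrix:
    """Center+normalize a test-by-train cross matrix with train statistics.

    ``row_self_raw`` holds the raw self-kernels k(x, x) of the test rows.
    The result has unit row/col self-kernels (stored in ``row_self``).
    """
    K_tx = KernelMatrix(
        list(K_tx_raw.row_ids), list(K_tx_raw.col_ids), K_tx_raw.values,
        row_self=np.asarray(row_self_raw, dtype=float),
    )
    Kc = center_cross(K_tx, stats.raw)
    return normalize(Kc, Kc.row_self, stats.centered_diag)
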