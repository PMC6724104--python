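"""Late fusion of kernel-regression models by structured-Hinge-loss
minimization.

Each of K component models (input kernel x output kernel x direction)
yields a compatibility score s_k(x, y) for a query/candidate pair; the
fused score is w^T s(x, y). The weight vector w minimizes

    J(w) = (lambda / 2) ||w||^2
           + (1 / ell) sum_i max_{y in Y_i} [ Delta(y_i, y)
                                              - w^T (s(x_i, y_i) - s(x_i, y)) ]

where Delta is the Hamming distance between molecular fingerprints (a
fraction of differing bits in [0, 1]). The max includes the true candidate
itself, whose term is exactly 0, so the loss is nonnegative: it is the
margin-rescaled convex upper bound on the top-1 error used in structured
SVMs. Optimization is mini-batch subgradient descent with step 1/(lambda k)
at global iteration k (Pegasos-style), starting from w = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import CandidateSets, FingerprintTable

logger = logging.getLogger("iokr")

__all__ = [
    "QueryScores",
    "ScoreTensor",
    "DeltaTable",
    "FusionModel",
    "hamming_delta",
    "build_delta_table",
    "hinge_loss",
    "objective",
    "train_sgd",
    "fuse_scores",
]


@dataclass
class QueryScores:
    """One query's candidate ids, (n_c, K) score matrix and truth index."""

    candidate_ids: list[str]
    scores: np.ndarray
    true_idx: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n_c = len(self.candidate_ids)
        if self.scores.ndim != 2 or self.scores.shape[0] != n_c:
            raise ValueError("score matrix shape does not match candidate list")
        if not (0 <= self.true_idx < n_c):
            raise ValueError("true-candidate index out of range")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite model scores")


@dataclass
class ScoreTensor:
    """Per-query stacks of per-model compatibility scores."""

    model_names: list[str]
    queries: dict[str, QueryScores]

    def __post_init__(self) -> None:
        K = len(self.model_names)
        for q, qs in self.queries.items():
            if qs.scores.shape[1] != K:
                raise ValueError(f"query {q!r}: expected {K} model scores")

    @property
    def n_models(self) -> int:
        return len(self.model_names)

    @property
    def query_ids(self) -> list[str]:
        return list(self.queries)


@dataclass
class DeltaTable:
    """Per-query structural distances Delta(y_i, y) aligned with the
    candidate lists; the entry at the true candidate is exactly 0."""

    deltas: dict[str, np.ndarray]


@dataclass
class FusionModel:
    """Learned combination weights plus the training hyperparameters."""

    model_names: list[str]
    w: np.ndarray
    lam: float
    batch_size: int
    epochs: int
    seed: int
    training_objective_trace: list[float] = field(default_factory=list)


def hamming_delta(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Fraction of fingerprint bits on which two molecules differ."""
    a = np.asarray(fp_a)
    b = np.asarray(fp_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("fingerprints must be nonempty vectors of equal length")
    return float(np.mean(a != b))


def build_delta_table(cands: CandidateSets, fps: FingerprintTable) -> DeltaTable:
    """Hamming distances from each query's true molecule to its candidates."""
    cands.validate_against(fps)
    deltas: dict[str, np.ndarray] = {}
    for q, clist in cands.candidates.items():
        if q in cands.unrankable:
            continue
        fp_true = fps.bits[cands.truth[q]]
        C = fps.matrix(clist)
        deltas[q] = np.mean(C != fp_true[None, :].astype(float), axis=1)
        deltas[q][clist.index(cands.truth[q])] = 0.0
    return DeltaTable(deltas)


def hinge_loss(
    w: np.ndarray, S_i: np.ndarray, delta_i: np.ndarray, true_idx: int
) -> tuple[float, int]:
    """Structured Hinge loss of one query and the index attaining the max.

    max_y Delta(y_i, y) - w^T (s(x_i, y_i) - s(x_i, y)); the max ranges over
    all candidates including the truth (whose term is 0), so the loss is
    nonnegative. Ties go to the lowest candidate index.
    """
    S_i = np.asarray(S_i, dtype=float)
    delta_i = np.asarray(delta_i, dtype=float)
    w = np.asarray(w, dtype=float)
    if S_i.shape[0] != delta_i.shape[0] or S_i.shape[1] != w.shape[0]:
        raise ValueError("shape mismatch between scores, deltas and weights")
    v = S_i @ w
    margins = delta_i - (v[true_idx] - v)
    j = int(np.argmax(margins))  # first max: lowest index on ties
    return float(margins[j]), j


def objective(
    w: np.ndarray, tensor: ScoreTensor, deltas: DeltaTable, lam: float
) -> float:
    """Regularized mean structured Hinge loss J(w)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    w = np.asarray(w, dtype=float)
    losses = [
        hinge_loss(w, qs.scores, deltas.deltas[q], qs.true_idx)[0]
        for q, qs in tensor.queries.items()
    ]
    return float(0.5 * lam * (w @ w) + np.mean(losses))


def train_sgd(
    tensor: ScoreTensor,
    deltas: DeltaTable,
    lam: float,
    m: int = 15,
    epochs: int = 30,
    seed: int = 0,
) -> FusionModel:
    """Learn fusion weights by mini-batch subgradient descent.

    Per batch B at global iteration k (starting at 1) the update is

        w <- w - (1 / (lambda k)) * (lambda w
              + (1/|B|) sum_{i in B} [s(x_i, y*_i) - s(x_i, y_i)])

    where y*_i is the argmax of query i's hinge (contribution zero when the
    hinge is inactive). w starts at zero; each epoch randomly permutes the
    queries into contiguous batches of size m (last batch smaller if needed).
    Identical inputs and seed give bit-identical weights. The per-epoch
    objective J(w) is recorded in ``training_objective_trace``.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0 for the 1/(lambda k) schedule")
    if m < 1:
        raise ValueError("batch size must be >= 1")
    qids = tensor.query_ids
    ell = len(qids)
    if m > ell:
        m = ell
    K = tensor.n_models
    rng = np.random.default_rng(seed)
    w = np.zeros(K)
    k = 1
    trace: list[float] = []
    for _ in range(epochs):
        perm = rng.permutation(ell)
        for start in range(0, ell, m):
            batch = perm[start:start + m]
            grad = lam * w.copy()
            hinge_grad = np.zeros(K)
            for idx in batch:
                qs = tensor.queries[qids[idx]]
                loss, j = hinge_loss(w, qs.scores, deltas.deltas[qids[idx]], qs.true_idx)
                if loss > 0 and j != qs.true_idx:
                    hinge_grad += qs.scores[j] - qs.scores[qs.true_idx]
            grad += hinge_grad / batch.size
            t = 1.0 / (lam * k)
            w = w - t * grad
            k += 1
        trace.append(objective(w, tensor, deltas, lam))
    return FusionModel(list(tensor.model_names), w, lam, m, epochs, seed, trace)


def fuse_scores(model: FusionModel, tensor: ScoreTensor) -> dict[str, np.ndarray]:
    """Fused score vector S_i w per query."""
    if tensor.n_models != model.w.shape[0]:
        raise ValueError("model count mismatch between weights and tensor")
    return {q: qs.scores @ model.w for q, qs in tensor.queries.items()}
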