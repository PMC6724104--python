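"""Structure-grouped cross-validation protocol: fit every (input kernel x
output kernel x direction) model on three folds, train the score-fusion
weights on a fourth, and measure top-k identification accuracy on the fifth.

Spectra of the same molecular structure share a group and therefore a fold,
so a test spectrum never has a training spectrum of the same molecule. Each
of the five rounds rotates the roles. All preprocessing statistics (kernel
centering/normalization), regularization and bandwidth selections and fusion
weights are computed strictly from the training/validation folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import CandidateSets, FingerprintTable, KernelMatrix
from . import kernels as kmod
from .forward import alpha, cosine_scores, fit_iokr, tune_lambda_by_mse
from .fusion import (
    DeltaTable,
    FusionModel,
    QueryScores,
    ScoreTensor,
    build_delta_table,
    fuse_scores,
    train_sgd,
)
from .reverse import beta, fit_reverse, reverse_cosine_scores, tune_lambda_by_mse_reverse

logger = logging.getLogger("iokr")

__all__ = [
    "CVPlan",
    "RankingResult",
    "FusionConfig",
    "ProtocolReport",
    "grouped_kfold",
    "rank_candidates",
    "topk_accuracy",
    "run_protocol",
]

DEFAULT_LAMBDA_GRID = tuple(10.0**e for e in range(-5, 2))
DEFAULT_GAMMA_GRID = tuple(10.0**e for e in range(-3, 2))
OUTPUT_KERNELS = ("linear", "tanimoto", "gaussian", "gaussian-tanimoto")


# ---------------------------------------------------------------------------
# CV plan


@dataclass
class CVPlan:
    """Fold assignment by structure group plus per-round fold roles."""

    n_folds: int
    assignment: dict[str, int]  # group_id -> fold
    rounds: list[tuple[list[int], int, int]]  # (train folds, validation, test)

    def fold_of(self, group_id: str) -> int:
        return self.assignment[group_id]


def grouped_kfold(group_ids: Sequence[str], n_folds: int = 5, seed: int = 0) -> CVPlan:
    """Deal structure groups to folds: shuffle with ``seed``, then round-robin.

    All spectra sharing a group land in the same fold; every fold serves as
    the test fold exactly once, with the next fold (cyclically) as the
    validation fold and the remaining folds as training folds.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    groups = list(dict.fromkeys(group_ids))  # first-seen order
    if len(groups) < n_folds:
        raise ValueError(f"{len(groups)} groups cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    assignment = {groups[g]: int(i % n_folds) for i, g in enumerate(order)}
    rounds = []
    for r in range(n_folds):
        val = (r + 1) % n_folds
        train = [f for f in range(n_folds) if f not in (r, val)]
        rounds.append((train, val, r))
    return CVPlan(n_folds, assignment, rounds)


# ---------------------------------------------------------------------------
# Ranking and accuracy


@dataclass
class RankingResult:
    """One query's candidates sorted by descending score, plus the truth's
    pessimistic rank (strictly-better candidates and all non-truth ties count
    ahead of the truth, so constant scores can never inflate accuracy)."""

    query_id: str
    ranked_ids: list[str]
    rank_of_truth: int
    scorable: bool = True


def rank_candidates(
    scores: np.ndarray, candidate_ids: Sequence[str], true_id: str, query_id: str = ""
) -> RankingResult:
    scores = np.asarray(scores, dtype=float)
    candidate_ids = list(candidate_ids)
    if true_id not in candidate_ids:
        logger.warning("query %s: truth absent from candidates; unscorable", query_id)
        order = np.argsort(-scores, kind="stable")
        return RankingResult(query_id, [candidate_ids[i] for i in order],
                             len(candidate_ids), scorable=False)
    t = candidate_ids.index(true_id)
    s_true = scores[t]
    better = int(np.sum(scores > s_true))
    ties = int(np.sum(scores == s_true)) - 1  # excluding the truth itself
    rank = 1 + better + ties
    order = np.argsort(-scores, kind="stable")
    return RankingResult(query_id, [candidate_ids[i] for i in order], rank)


def topk_accuracy(results: Sequence[RankingResult], ks: Sequence[int]) -> dict[int, float]:
    """Percentage of scorable queries whose truth ranks within the top k."""
    scorable = [r for r in results if r.scorable]
    if not scorable:
        raise ValueError("no scorable ranking results")
    n_dropped = len(results) - len(scorable)
    if n_dropped:
        logger.info("%d unscorable queries excluded from accuracy", n_dropped)
    return {
        int(k): 100.0 * sum(r.rank_of_truth <= k for r in scorable) / len(scorable)
        for k in ks
    }


# ---------------------------------------------------------------------------
# Protocol configuration and report


@dataclass(frozen=True)
class FusionConfig:
    """Hyperparameters of the score-aggregation learner."""

    lambda_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
    batch_size: int = 15
    epochs: int = 30
    inner_folds: int = 4


@dataclass
class RoundReport:
    round_idx: int
    selected_lambdas: dict[str, float]
    selected_gammas: dict[str, float]
    fusion_lambda: float
    fusion_weights: np.ndarray
    fusion_trace: list[float]
    test_topk: dict[str, dict[int, float]]
    n_test: int


@dataclass
class ProtocolReport:
    """Averaged top-k tables plus per-round hyperparameters and weights."""

    model_names: list[str]
    topk: dict[str, dict[int, float]]  # method -> k -> averaged %
    rounds: list[RoundReport] = field(default_factory=list)

    @property
    def mean_fusion_weights(self) -> np.ndarray:
        return np.mean([r.fusion_weights for r in self.rounds], axis=0)


# ---------------------------------------------------------------------------
# Output-kernel helpers


def _output_kernel(
    name: str,
    fps: FingerprintTable,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    gamma: float | None,
) -> KernelMatrix:
    if name == "linear":
        return kmod.linear_fp_kernel(fps, row_ids, col_ids)
    if name == "tanimoto":
        return kmod.tanimoto_kernel(fps, row_ids, col_ids)
    if name == "gaussian":
        return kmod.gaussian_fp_kernel(fps, row_ids, col_ids, kmod.GaussianParams(gamma))
    if name == "gaussian-tanimoto":
        return kmod.gaussian_tanimoto_kernel(
            fps, row_ids, col_ids, kmod.GaussianParams(gamma)
        )
    raise ValueError(f"unknown output kernel {name!r}")


def _raw_output_self(name: str, fps: FingerprintTable, ids: Sequence[str]) -> np.ndarray:
    if name == "linear":
        return (fps.matrix(ids) ** 2).sum(axis=1)
    return np.ones(len(ids))  # tanimoto / gaussian variants are 1 on the diagonal


def _output_sq_distances(name: str, fps: FingerprintTable, ids: Sequence[str]) -> np.ndarray:
    """Condensed off-diagonal squared feature distances for entropy tuning."""
    A = fps.matrix(ids)
    if name == "gaussian":
        sq = (A[:, None, :] != A[None, :, :]).sum(axis=2).astype(float)
    elif name == "gaussian-tanimoto":
        sq = 2.0 - 2.0 * kmod._tanimoto_values(A, A)
    else:
        raise ValueError(name)
    iu = np.triu_indices(len(ids), k=1)
    return sq[iu]


def _select_gamma(name: str, fps: FingerprintTable, train_mols: Sequence[str],
                  gamma_grid: Sequence[float]) -> float | None:
    if name not in ("gaussian", "gaussian-tanimoto"):
        return None
    d2 = _output_sq_distances(name, fps, train_mols)
    return kmod.select_gamma_by_entropy(d2, gamma_grid).gamma


# ---------------------------------------------------------------------------
# The full protocol


def _slice_gram(K: KernelMatrix, row_ids: Sequence[str], col_ids: Sequence[str]
                ) -> KernelMatrix:
    idx = {qid: i for i, qid in enumerate(K.row_ids)}
    ri = [idx[q] for q in row_ids]
    ci = [idx[q] for q in col_ids]
    return KernelMatrix(list(row_ids), list(col_ids), K.values[np.ix_(ri, ci)])


def _tensor_from_scores(
    model_names: list[str],
    per_model: dict[str, dict[str, np.ndarray]],
    queries: Sequence[str],
    cands: CandidateSets,
) -> ScoreTensor:
    entries = {}
    for q in queries:
        if q in cands.unrankable:
            continue
        clist = cands.candidates[q]
        S = np.column_stack([per_model[m][q] for m in model_names])
        entries[q] = QueryScores(list(clist), S, clist.index(cands.truth[q]))
    return ScoreTensor(list(model_names), entries)


def _select_fusion_lambda(
    tensor: ScoreTensor, deltas: DeltaTable, cfg: FusionConfig, seed: int
) -> float:
    """Inner-CV grid search maximizing top-1 accuracy; ties to larger lambda."""
    qids = tensor.query_ids
    if len(qids) < cfg.inner_folds or len(cfg.lambda_grid) == 1:
        return max(cfg.lambda_grid)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(qids))
    folds = np.array_split(perm, cfg.inner_folds)
    best_lam, best_acc = None, -1.0
    for lam in sorted(cfg.lambda_grid):
        hits, total = 0, 0
        for f in folds:
            hold = {qids[i] for i in f}
            tr = ScoreTensor(tensor.model_names,
                             {q: tensor.queries[q] for q in qids if q not in hold})
            if not tr.queries or not hold:
                continue
            model = train_sgd(tr, deltas, lam, cfg.batch_size, cfg.epochs, seed)
            for q in hold:
                qs = tensor.queries[q]
                fused = qs.scores @ model.w
                r = rank_candidates(fused, qs.candidate_ids,
                                    qs.candidate_ids[qs.true_idx], q)
                hits += r.rank_of_truth == 1
                total += 1
        acc = hits / max(total, 1)
        if acc >= best_acc:  # >= so ties promote the larger lambda
            best_acc = acc
            best_lam = lam
    return best_lam  # type: ignore[return-value]


def run_protocol(
    input_grams: Mapping[str, KernelMatrix],
    fingerprints: FingerprintTable,
    cands: CandidateSets,
    groups: Mapping[str, str],
    output_kernels: Sequence[str] = ("linear", "tanimoto"),
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    fusion: FusionConfig = FusionConfig(),
    ks: Sequence[int] = (1, 5, 10),
    n_folds: int = 5,
    seed: int = 0,
) -> ProtocolReport:
    """Run the full grouped-CV identification benchmark.

    Parameters
    ----------
    input_grams : mapping name -> raw square KernelMatrix
        One raw (uncentered) input Gram matrix per input-kernel view, over
        identical query/spectrum ids (the keys of ``cands``).
    fingerprints : FingerprintTable
        Fingerprints for all true molecules and candidates.
    cands : CandidateSets
        Per-query candidate lists with the truth marked.
    groups : mapping query id -> group id
        Structure groups used for fold assignment.

    Every round fits all (input x output x direction) models on the three
    training folds (ridge parameter tuned by inner-CV MSE, Gaussian bandwidth
    by entropy maximization on the training fold), scores the validation and
    test candidates, learns fusion weights on the validation fold (fusion
    lambda by inner 4-fold top-1 accuracy) and evaluates single models,
    Unimkl variants and the fused model on the test fold.
    """
    cands.validate_against(fingerprints)
    for name in output_kernels:
        if name not in OUTPUT_KERNELS:
            raise ValueError(f"unknown output kernel {name!r}")
    query_ids = list(cands.candidates)
    for name, K in input_grams.items():
        if sorted(K.row_ids) != sorted(query_ids):
            raise ValueError(f"input gram {name!r} ids do not match the queries")
    logger.info("protocol seed=%d, %d queries, %d views", seed, len(query_ids),
                len(input_grams))

    plan = grouped_kfold([groups[q] for q in query_ids], n_folds, seed)
    fold_of = {q: plan.fold_of(groups[q]) for q in query_ids}
    deltas_all = build_delta_table(cands, fingerprints)

    model_names = [
        f"{v}|{o}|{d}"
        for v in input_grams
        for o in output_kernels
        for d in ("forward", "reverse")
    ]
    methods = model_names + [f"unimkl|{o}" for o in output_kernels] + ["fusion"]
    collected: dict[str, list[RankingResult]] = {m: [] for m in methods}
    rounds: list[RoundReport] = []

    for train_folds, val_fold, test_fold in plan.rounds:
        train_q = [q for q in query_ids if fold_of[q] in train_folds]
        val_q = [q for q in query_ids if fold_of[q] == val_fold]
        test_q = [q for q in query_ids if fold_of[q] == test_fold]
        eval_q = val_q + test_q
        train_mols = [cands.truth[q] for q in train_q]
        cand_union = cands.all_candidate_ids(eval_q)
        round_start = {m: len(collected[m]) for m in methods}
        sel_lambdas: dict[str, float] = {}
        sel_gammas: dict[str, float] = {}

        # --- input-kernel preprocessing (train statistics only)
        in_stats: dict[str, kmod.TrainKernelStats] = {}
        in_cross: dict[str, np.ndarray] = {}  # eval x train, processed
        for v, G in input_grams.items():
            stats = kmod.preprocess_train(_slice_gram(G, train_q, train_q))
            raw_cross = _slice_gram(G, eval_q, train_q)
            idx = {qid: i for i, qid in enumerate(G.row_ids)}
            raw_self = np.array([G.values[idx[q], idx[q]] for q in eval_q])
            in_stats[v] = stats
            in_cross[v] = kmod.preprocess_cross(raw_cross, raw_self, stats).values

        # --- output-kernel preprocessing
        out_stats: dict[str, kmod.TrainKernelStats] = {}
        out_cand_cross: dict[str, np.ndarray] = {}  # train x candidate, processed
        for o in output_kernels:
            gamma = _select_gamma(o, fingerprints, train_mols, gamma_grid)
            if gamma is not None:
                sel_gammas[o] = gamma
            stats = kmod.preprocess_train(
                _output_kernel(o, fingerprints, train_mols, train_mols, gamma)
            )
            raw_cross = _output_kernel(o, fingerprints, cand_union, train_mols, gamma)
            raw_self = _raw_output_self(o, fingerprints, cand_union)
            cross = kmod.preprocess_cross(raw_cross, raw_self, stats)
            out_stats[o] = stats
            out_cand_cross[o] = cross.values.T  # train x candidate
        cand_pos = {c: i for i, c in enumerate(cand_union)}
        eval_pos = {q: i for i, q in enumerate(eval_q)}

        # --- fit and score every (view, output, direction) model
        per_model: dict[str, dict[str, np.ndarray]] = {}
        for v in input_grams:
            KX = in_stats[v].processed
            for o in output_kernels:
                KY = out_stats[o].processed
                cand_cross = out_cand_cross[o]
                unit_self = np.ones(len(cand_union))

                lam_h = tune_lambda_by_mse(KX, KY, lambda_grid, seed=seed)
                sel_lambdas[f"{v}|{o}|forward"] = lam_h
                fmodel = fit_iokr(KX, KY, lam_h)
                A = alpha(fmodel, in_cross[v].T)  # (ell, n_eval)
                fscores: dict[str, np.ndarray] = {}
                for q in eval_q:
                    cidx = [cand_pos[c] for c in cands.candidates[q]]
                    fscores[q] = cosine_scores(
                        A[:, eval_pos[q]], fmodel, cand_cross[:, cidx],
                        unit_self[cidx],
                    )
                per_model[f"{v}|{o}|forward"] = fscores

                lam_g = tune_lambda_by_mse_reverse(KY, KX, lambda_grid, seed=seed)
                sel_lambdas[f"{v}|{o}|reverse"] = lam_g
                rmodel = fit_reverse(KY, KX, lam_g)
                B = beta(rmodel, cand_cross)  # (ell, n_cand_union)
                rscores: dict[str, np.ndarray] = {}
                for q in eval_q:
                    cidx = [cand_pos[c] for c in cands.candidates[q]]
                    rscores[q] = reverse_cosine_scores(
                        B[:, cidx], rmodel, in_cross[v][eval_pos[q]], 1.0
                    )
                per_model[f"{v}|{o}|reverse"] = rscores

        # --- Unimkl early-fusion baselines (forward direction)
        uni = kmod.unimkl_combine([in_stats[v].processed for v in input_grams])
        uni_K = kmod.normalize(uni)
        uni_cross = np.mean([in_cross[v] for v in input_grams], axis=0)
        for o in output_kernels:
            KY = out_stats[o].processed
            lam_u = tune_lambda_by_mse(uni_K, KY, lambda_grid, seed=seed)
            sel_lambdas[f"unimkl|{o}"] = lam_u
            umodel = fit_iokr(uni_K, KY, lam_u)
            A = alpha(umodel, uni_cross.T)
            unit_self = np.ones(len(cand_union))
            for q in test_q:
                cidx = [cand_pos[c] for c in cands.candidates[q]]
                s = cosine_scores(A[:, eval_pos[q]], umodel,
                                  out_cand_cross[o][:, cidx], unit_self[cidx])
                collected[f"unimkl|{o}"].append(
                    rank_candidates(s, cands.candidates[q], cands.truth[q], q)
                )

        # --- single-model test rankings
        for name in model_names:
            for q in test_q:
                collected[name].append(
                    rank_candidates(per_model[name][q], cands.candidates[q],
                                    cands.truth[q], q)
                )

        # --- late fusion: train on validation fold, evaluate on test fold
        val_tensor = _tensor_from_scores(model_names, per_model, val_q, cands)
        test_tensor = _tensor_from_scores(model_names, per_model, test_q, cands)
        lam_f = _select_fusion_lambda(val_tensor, deltas_all, fusion, seed)
        fus = train_sgd(val_tensor, deltas_all, lam_f, fusion.batch_size,
                        fusion.epochs, seed)
        fused = fuse_scores(fus, test_tensor)
        for q, s in fused.items():
            collected["fusion"].append(
                rank_candidates(s, cands.candidates[q], cands.truth[q], q)
            )

        round_topk = {
            m: topk_accuracy(collected[m][round_start[m]:], ks)
            for m in methods
            if len(collected[m]) > round_start[m]
        }
        rounds.append(
            RoundReport(test_fold, sel_lambdas, sel_gammas, lam_f, fus.w,
                        fus.training_objective_trace, round_topk, len(test_q))
        )
        logger.info("round %d done (test fold %d, %d queries)",
                    len(rounds), test_fold, len(test_q))

    topk = {m: topk_accuracy(results, ks) for m, results in collected.items() if results}
    return ProtocolReport(model_names, topk, rounds)
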