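"""Compare the two regression directions on one synthetic split.

The forward direction predicts a fingerprint embedding from the spectrum and
ranks candidates in the fingerprint space; the reverse direction predicts a
spectrum embedding for every candidate and ranks them in the spectrum space
(one coefficient solve per candidate, which is why it is the slower
direction). Both print training-free test top-1 accuracy; on signal-bearing
data both should sit far above the 1/n_c chance level.
"""

import numpy as np

from iokr import (
    GeneratorConfig, PPKParams, alpha, beta, cosine_scores, fit_iokr,
    fit_reverse, generate_benchmark, linear_fp_kernel, ppk_matrix,
    preprocess_cross, preprocess_train, rank_candidates,
    reverse_cosine_scores, topk_accuracy,
)

bench = generate_benchmark(GeneratorConfig(n_molecules=60, candidates_per_query=8,
                                           n_views=1, seed=4))
cands, fps = bench.candidates, bench.fingerprints
spectra = {s.id: s for s in bench.spectra_views["view1"]}
qids = bench.query_ids
train_q, test_q = qids[:40], qids[40:]
train_sp = [spectra[q] for q in train_q]
train_mols = [cands.truth[q] for q in train_q]

ppk = PPKParams(0.5, 0.2)
x_stats = preprocess_train(ppk_matrix(train_sp, train_sp, ppk))
y_stats = preprocess_train(linear_fp_kernel(fps, train_mols, train_mols))

test_sp = [spectra[q] for q in test_q]
raw_self = np.array([ppk_matrix([s], [s], ppk).values[0, 0] for s in test_sp])
k_test = preprocess_cross(ppk_matrix(test_sp, train_sp, ppk), raw_self, x_stats).values

cand_union = cands.all_candidate_ids(test_q)
cpos = {c: i for i, c in enumerate(cand_union)}
y_cross = preprocess_cross(
    linear_fp_kernel(fps, cand_union, train_mols),
    (fps.matrix(cand_union) ** 2).sum(1), y_stats,
).values.T  # train x candidates

lam = 1e-3
fwd = fit_iokr(x_stats.processed, y_stats.processed, lam)
rev = fit_reverse(y_stats.processed, x_stats.processed, lam)
B = beta(rev, y_cross)  # one multi-RHS solve for the whole candidate union

f_res, r_res = [], []
for i, q in enumerate(test_q):
    ci = [cpos[c] for c in cands.candidates[q]]
    ones = np.ones(len(ci))
    fs = cosine_scores(alpha(fwd, k_test[i]), fwd, y_cross[:, ci], ones)
    rs = reverse_cosine_scores(B[:, ci], rev, k_test[i], 1.0)
    f_res.append(rank_candidates(fs, cands.candidates[q], cands.truth[q], q))
    r_res.append(rank_candidates(rs, cands.candidates[q], cands.truth[q], q))

chance = 100.0 / bench.cfg.candidates_per_query
print(f"test queries: {len(test_q)}, candidates each: "
      f"{bench.cfg.candidates_per_query} (chance top-1 = {chance:.1f}%)")
print(f"forward  top-1: {topk_accuracy(f_res, [1])[1]:.1f}%")
print(f"reverse  top-1: {topk_accuracy(r_res, [1])[1]:.1f}%")
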