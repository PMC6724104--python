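"""Identify a query spectrum against a candidate list, starting from files.

Writes a tiny dataset (MGF spectra, fingerprint table, candidate table) to a
temporary directory, reads it back through the package's parsers, builds the
probability product kernel on spectra and a Tanimoto kernel on fingerprints,
fits the spectrum-to-fingerprint regression, and ranks each query's
candidates by cosine score. Higher score = predicted fingerprint closer to
the candidate's; the printed rank of the true molecule is what top-k
accuracy counts.
"""

import tempfile
from pathlib import Path

import numpy as np

from iokr import (
    GeneratorConfig, PPKParams, alpha, cosine_scores, fit_iokr,
    generate_benchmark, ppk_matrix, preprocess_cross, preprocess_train,
    rank_candidates, read_candidate_sets, read_fingerprints, read_mgf,
    tanimoto_kernel, write_candidate_sets, write_fingerprints, write_mgf,
)

# --- create and reload a small dataset (stands in for user files)
bench = generate_benchmark(GeneratorConfig(n_molecules=30, candidates_per_query=6,
                                           n_views=1, seed=3))
tmp = Path(tempfile.mkdtemp())
write_mgf(bench.spectra_views["view1"], tmp / "spectra.mgf")
write_fingerprints(bench.fingerprints, tmp / "fingerprints.tsv")
write_candidate_sets(bench.candidates, tmp / "candidates.tsv")

spectra = read_mgf(tmp / "spectra.mgf")
fps = read_fingerprints(tmp / "fingerprints.tsv")
cands = read_candidate_sets(tmp / "candidates.tsv")

# --- train on the first 20 molecules, query the remaining 10
train, test = spectra[:20], spectra[20:]
train_ids = [s.id for s in train]
train_mols = [cands.truth[q] for q in train_ids]

ppk = PPKParams(sigma_m=0.5, sigma_i=0.2)
x_stats = preprocess_train(ppk_matrix(train, train, ppk))
y_stats = preprocess_train(tanimoto_kernel(fps, train_mols, train_mols))
model = fit_iokr(x_stats.processed, y_stats.processed, lambda_h=1e-3)

raw_cross = ppk_matrix(test, train, ppk)
raw_self = np.array([ppk_matrix([s], [s], ppk).values[0, 0] for s in test])
k_test = preprocess_cross(raw_cross, raw_self, x_stats).values

print(f"{'query':>10} {'truth':>10} rank  top candidates")
for i, s in enumerate(test):
    clist = cands.candidates[s.id]
    raw = tanimoto_kernel(fps, clist, train_mols)
    cross = preprocess_cross(raw, np.ones(len(clist)), y_stats).values.T
    scores = cosine_scores(alpha(model, k_test[i]), model, cross, np.ones(len(clist)))
    r = rank_candidates(scores, clist, cands.truth[s.id], s.id)
    print(f"{s.id:>10} {cands.truth[s.id]:>10} {r.rank_of_truth:>4}  {r.ranked_ids[:3]}")
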