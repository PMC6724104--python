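# Methods

## Model

Both regression directions are kernel ridge regressions between two
reproducing-kernel Hilbert spaces. Let {(xᵢ, yᵢ)}ᵢ₌₁..ℓ be training pairs of
an MS/MS spectrum and its molecule, ϕ/ψ the (implicit) input/output feature
maps, K_X and K_Y the training Gram matrices.

**Forward.** h minimizing Σᵢ‖h(xᵢ) − ψ(yᵢ)‖² + λ_h‖h‖² has the representer
form h(x) = Σᵢ αᵢ(x) ψ(yᵢ), α(x) = (λ_h I + K_X)⁻¹ k_X^x. Candidates y of a
query are ranked by ‖h(x) − ψ(y)‖² = αᵀK_Yα + k_y(y,y) − 2αᵀk_Y^y, or for
fusion by the cosine αᵀk_Y^y / (√(αᵀK_Yα) √(k_y(y,y))). The linear operator
behind h is never materialized; everything is evaluated through the Gram
matrices.

**Reverse.** The same regression with the roles of the two spaces swapped:
β(y) = (λ_g I + K_Y)⁻¹ k_Y^y, candidates ranked by
β(y)ᵀK_Xβ(y) + k_x(x,x) − 2β(y)ᵀk_X^x in the input space. Per-query cost
grows with the candidate count (one coefficient column per candidate), so β
is computed once for the union of a fold's candidates in a single
multi-right-hand-side solve and reused across queries.

**Late fusion.** Given K component models' cosine scores s(x,y) ∈ ℝᴷ, the
combination weight w minimizes the margin-rescaled structured Hinge
objective J(w) = (λ/2)‖w‖² + (1/ℓ)Σᵢ max_{y∈Yᵢ} [Δ(yᵢ,y) − wᵀ(s(xᵢ,yᵢ) −
s(xᵢ,y))], Δ being the fractional Hamming distance between the candidates'
binary fingerprints (so Δ ∈ [0,1] and Δ = 0 at the truth, making the loss a
convex upper bound on the top-1 error). Optimization is mini-batch
subgradient descent: w starts at zero, each epoch randomly permutes the
queries into contiguous batches of size m, the step at global iteration k
(counted from 1 across epochs) is t = 1/(λk), and the per-batch update
applies the subgradient λw + (1/|B|)Σᵢ [s(xᵢ,y*ᵢ) − s(xᵢ,yᵢ)] with y* the
argmax of the hinge (zero contribution when the hinge is inactive). This is
the standard Pegasos update for J(w); the per-epoch value of J is recorded
so training can be audited. There is no projection, averaging or early
stopping. Ties in the argmax break to the lowest candidate index, which
with a fixed batching seed makes training bit-reproducible.

## Kernels and preprocessing

- **Probability product kernel** on peak lists: each peak is a 2-D Gaussian
  in (m/z, intensity) with standard deviations σ_m (Da) and σ_i (intensity
  units); k(x,x′) = (1/(n_x n_x′ 4π σ_m σ_i)) Σ_{ℓℓ′} exp(−Δm²/4σ_m²)
  exp(−Δi²/4σ_i²). Intensities are rescaled to max 1 per spectrum before
  evaluation (configurable off); σ_m and σ_i are required configuration
  with no hidden defaults. The package's own runs use σ_m = 0.5 Da,
  σ_i = 0.2 — loose tolerances appropriate to the generator's noise scale.
- **Fingerprint kernels**: linear (shared-bit count), Tanimoto (|∩|/|∪|,
  with 0/0 for two all-zero fingerprints defined as 1 and logged), Gaussian
  exp(−γ·Hamming count), and Gaussian on the Tanimoto feature-space
  distance exp(−γ(2 − 2k_tan)).
- **γ selection**: for each grid value, the off-diagonal kernel values are
  binned into 100 equal-width bins on [0,1] and the Shannon entropy of the
  bin histogram is computed; the entropy-maximizing γ wins, ties to the
  smaller γ. Bin count and tie rule are this package's conventions; other
  entropy estimators would be defensible.
- **Centering and normalization**: training Gram matrices are centered in
  feature space (row/column sums vanish) and then cosine-normalized (unit
  diagonal) — the normalized-centered kernel is the cosine in centered
  feature space. Test-by-train cross matrices are centered with *training*
  means only and normalized with the centered self-kernels of both sides;
  running the training matrix through the cross pipeline reproduces the
  trained preprocessing exactly. Note the four-term cross centering makes
  every cross *row* sum to zero identically (the train column means sum to
  the grand mean); the column sums over test points do not vanish.
  Double centering is refused rather than silently absorbed.
- **Unimkl**: the uniform multiple-kernel baseline is the entrywise mean of
  the centered+normalized input kernels, re-normalized; ranking is
  invariant to the overall scale, so mean versus sum is immaterial.

## Hyperparameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| λ_h, λ_g | ridge regularization | tuned on grid 10⁻⁵…10¹ | inner-CV kernel-trick MSE, ties to the larger λ |
| γ | Gaussian output-kernel bandwidth | entropy-maximal on grid 10⁻³…10¹ | see above |
| λ (fusion) | hinge regularization | grid 10⁻⁴…1, top-1-maximal by inner 4-fold CV on the validation fold, ties to the larger λ | the 1/(λk) schedule requires λ > 0 |
| m | fusion batch size | 15 | small batches, several updates per epoch |
| epochs | fusion passes | 30 | fixed; no early stopping |

Solves of (λI + K) use a Cholesky factorization; centered kernels are
singular by construction (rank ≤ ℓ−1) and λ > 0 restores definiteness, so a
single jitter of 1e-10·trace/ℓ guards round-off only, after which failure
is raised loudly. Slightly negative squared distances from round-off are
clipped to zero at debug-log level. Degenerate norms (‖h(x)‖² or ‖g(y)‖² ≤
1e-12) yield zero cosine scores with a warning rather than NaNs.

Ranking is pessimistic under ties: the truth's rank counts every strictly
better candidate *and* every non-truth candidate tied with it, so constant
or duplicated scores can never inflate top-k accuracy. Queries whose truth
is missing from their candidate list are flagged, excluded from accuracy
denominators, and counted in the log.

## Synthetic benchmark

The generator couples structure to spectrum through a fragment dictionary:
every fingerprint bit owns `peaks_per_active_bit` characteristic masses
drawn uniformly from `mass_range`, and a molecule's spectrum emits the
masses of its active bits with Gaussian m/z jitter (`mass_noise_sd`),
intensity |1 + N(0, `intensity_noise_sd`)|, independent peak dropout, and
`n_noise_peaks` uniform background peaks. Fingerprint bits live in
`n_blocks` blocks driven by shared latent Bernoulli variables (coupling
0.75), so within-block bits correlate while the marginal activation rate
stays at `bit_activation_prob`. Candidate sets hold the truth, ⌈(n_c−1)/2⌉
near decoys (truth with `near_decoy_flip_bits` bits flipped) and far decoys
drawn fresh from the fingerprint distribution under new ids — fresh draws,
not pool copies, so that decoys bear no incidental relation to any training
fold and a no-signal dataset scores exactly at the 1/n_c chance level.
Multiple "views" re-draw the fragment dictionary and noise independently
over the same molecules, playing the role that distinct input kernels play
on real data. All randomness flows from one master seed through named child
streams.

Default conditions: 80 molecules, 64 bits in 16 blocks, activation 0.3, two
peaks per active bit on 100–1000 Da, σ(mass) = 0.5 Da, σ(intensity) = 0.2,
dropout 0.1, 3 background peaks, 10 candidates per query with 4-bit near
decoys, two views. These sizes keep a full 5-fold protocol run in the
low seconds while leaving all methods clearly separated from chance.

What the generator does *not* emulate: isotope patterns, adducts,
collision-energy dependence, instrument-specific noise, shared
substructures causing correlated fragment masses across molecules, and
realistic candidate retrieval by molecular formula. Passing tests therefore
demonstrate the correctness and internal consistency of the machinery and
its qualitative behaviour (signal monotonicity, fusion benefits), not
identification rates transferable to real spectra.

## Design choices on open points

- Inner-CV MSE for λ reuses submatrices of the already centered+normalized
  training Gram rather than re-centering per inner split; the selection
  only needs a consistent relative error measure across the grid.
- The per-example objective of the fusion learner contains an ℓ-scaled
  regularization term; it is read as bookkeeping canceling the 1/ℓ of the
  full objective, so the implemented update is the plain Pegasos step for
  J(w) — the audited quantity is J itself.
- Spectra carry a `GROUPID` MGF header for the structure group used in fold
  assignment, defaulting to the spectrum id. How spectra measured at
  different collision energies are merged is left to the data producer.
- The evaluation report exposes per-round selected hyperparameters, fusion
  weights and the per-epoch objective trace, which is what the leak-freedom
  test compares bit-for-bit under test-fold corruption.

## Known limitations

- The reverse direction's candidate coefficient cache assumes candidate
  sets recur across queries; pathological datasets with fully disjoint,
  very large candidate sets lose that benefit.
- The fusion learner offers no slack-rescaling variant and no nonlinear
  combination.
- Fragmentation-tree input kernels are supported only as precomputed
  matrices; the package does not compute fragmentation trees.
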