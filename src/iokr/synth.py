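"""Synthetic benchmark generator: fingerprints, spectra and candidate sets
with a controllable input/output dependence.

Real MS/MS data couple a molecule's structure to its fragment peaks through
the fragmentation process. The generator emulates that coupling with a
fragment dictionary: every fingerprint bit owns a few characteristic masses
(drawn once per view), and a molecule's spectrum emits the masses of its
active bits with Gaussian m/z jitter, noisy intensities, random peak dropout
and uniform background peaks. Multiple "views" (independent fragment
dictionaries and noise draws over the same molecules) stand in for multiple
input kernels on the same data.

Candidate sets mimic same-molecular-formula database retrieval: each query's
list holds the true molecule, near decoys (the truth's fingerprint with a few
bits flipped) and far decoys (fresh fingerprints from the same distribution,
under fresh ids), so difficulty is controlled by the flip count and the
candidate count.

All randomness flows from a single master seed through named child streams
(fingerprints, per-view fragment tables, per-spectrum noise, candidates), so
each part can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import CandidateSets, FingerprintTable, Spectrum

logger = logging.getLogger("iokr")

__all__ = [
    "GeneratorConfig",
    "SyntheticBenchmark",
    "sample_fingerprints",
    "make_fragment_table",
    "spectrum_from_fingerprint",
    "make_candidate_sets",
    "generate_benchmark",
]

# within-block probability that a bit copies the block's latent state
_BLOCK_COUPLING = 0.75


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic benchmark.

    Defaults are sized for a desk-scale benchmark: 80 molecules with 64-bit
    fingerprints in 16 correlated blocks, two characteristic peaks per active
    bit in the 100-1000 Da range, mild mass/intensity noise, 10 candidates
    per query with 4-bit near decoys, and two independent input views.
    """

    n_molecules: int = 80
    d_bits: int = 64
    n_blocks: int = 16
    bit_activation_prob: float = 0.3
    peaks_per_active_bit: int = 2
    mass_range: tuple[float, float] = (100.0, 1000.0)
    mass_noise_sd: float = 0.5
    intensity_noise_sd: float = 0.2
    peak_dropout_prob: float = 0.1
    n_noise_peaks: int = 3
    candidates_per_query: int = 10
    near_decoy_flip_bits: int = 4
    n_views: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bit_activation_prob", "peak_dropout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_molecules", "d_bits", "n_blocks", "peaks_per_active_bit",
                     "candidates_per_query", "n_views"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.candidates_per_query < 2:
            raise ValueError("candidates_per_query must be >= 2")
        if self.d_bits < self.n_blocks:
            raise ValueError("d_bits must be >= n_blocks")
        if self.mass_range[0] >= self.mass_range[1]:
            raise ValueError("mass_range must satisfy m_lo < m_hi")
        if self.mass_noise_sd < 0 or self.intensity_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_noise_peaks < 0 or self.near_decoy_flip_bits < 0:
            raise ValueError("counts must be >= 0")


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def _block_index(cfg: GeneratorConfig) -> np.ndarray:
    sizes = np.diff(np.linspace(0, cfg.d_bits, cfg.n_blocks + 1).astype(int))
    return np.repeat(np.arange(cfg.n_blocks), sizes)


def _draw_fp(cfg: GeneratorConfig, rng: np.random.Generator,
             block_of: np.ndarray) -> np.ndarray:
    p = cfg.bit_activation_prob
    latent = rng.random(cfg.n_blocks) < p
    copy = rng.random(cfg.d_bits) < _BLOCK_COUPLING
    indep = rng.random(cfg.d_bits) < p
    return np.where(copy, latent[block_of], indep).astype(np.uint8)


def sample_fingerprints(cfg: GeneratorConfig, rng: np.random.Generator | None = None
                        ) -> FingerprintTable:
    """Draw duplicate-free binary fingerprints with block-correlated bits.

    Bits are partitioned into ``n_blocks`` contiguous blocks; within a block
    each bit copies a shared latent Bernoulli(bit_activation_prob) state with
    probability 0.75 and is an independent Bernoulli otherwise, so marginal
    activation stays at ``bit_activation_prob`` while within-block bits
    correlate. With n_blocks == d_bits the bits are fully independent.
    """
    if rng is None:
        rng = _child_rng(cfg.seed, 0)
    block_of = _block_index(cfg)
    ids, bits, seen = [], {}, set()
    for i in range(cfg.n_molecules):
        for _attempt in range(100):
            v = _draw_fp(cfg, rng, block_of)
            key = v.tobytes()
            if key not in seen:
                break
        else:
            raise RuntimeError("could not draw a duplicate-free fingerprint in 100 tries")
        seen.add(key)
        mid = f"mol{i+1:04d}"
        ids.append(mid)
        bits[mid] = v
    return FingerprintTable(ids, cfg.d_bits, bits)


def make_fragment_table(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """(d_bits, peaks_per_active_bit) characteristic masses, one row per bit."""
    lo, hi = cfg.mass_range
    return rng.uniform(lo, hi, size=(cfg.d_bits, cfg.peaks_per_active_bit))


def spectrum_from_fingerprint(
    spectrum_id: str,
    group_id: str,
    fp: np.ndarray,
    fragment_table: np.ndarray,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> Spectrum:
    """Emit a noisy spectrum for one molecule.

    Each active bit contributes its characteristic masses with Gaussian m/z
    jitter and intensity |1 + N(0, intensity_noise_sd)|; every signal peak is
    dropped independently with ``peak_dropout_prob``; ``n_noise_peaks``
    uniform background peaks are added. At least one peak is guaranteed (a
    background peak is forced if everything was dropped).
    """
    lo, hi = cfg.mass_range
    active = np.nonzero(np.asarray(fp) > 0)[0]
    masses: list[float] = []
    intens: list[float] = []
    if active.size:
        sig_m = fragment_table[active].ravel()
        sig_m = sig_m + rng.normal(0.0, cfg.mass_noise_sd, sig_m.size)
        sig_i = np.abs(1.0 + rng.normal(0.0, cfg.intensity_noise_sd, sig_m.size))
        keep = rng.random(sig_m.size) >= cfg.peak_dropout_prob
        masses.extend(sig_m[keep])
        intens.extend(sig_i[keep])
    n_noise = cfg.n_noise_peaks
    if not masses and n_noise == 0:
        n_noise = 1
    if n_noise:
        masses.extend(rng.uniform(lo, hi, n_noise))
        intens.extend(rng.uniform(0.05, 0.5, n_noise))
    mz = np.clip(np.asarray(masses), 1e-6, None)
    return Spectrum(id=spectrum_id, group_id=group_id,
                    mz=mz, intensity=np.asarray(intens))


def make_candidate_sets(
    fps: FingerprintTable, cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[CandidateSets, FingerprintTable]:
    """Build per-query candidate sets and the enlarged fingerprint table.

    Each query (one per molecule) gets the truth plus a roughly half/half mix
    of near decoys (truth with ``near_decoy_flip_bits`` random bits flipped)
    and far decoys (fresh fingerprints drawn from the same block-correlated
    distribution as the pool). Decoys are appended to a copy of the table
    under fresh ids; pool molecules are never reused as decoys, so candidate
    difficulty is controlled by the flip count and the candidate count alone
    and decoys carry no incidental relationship to any training fold.
    """
    if rng is None:
        rng = _child_rng(cfg.seed, 3)
    n_c = cfg.candidates_per_query
    block_of = _block_index(cfg)
    pool = list(fps.ids)
    out = FingerprintTable(list(fps.ids), fps.d, dict(fps.bits))
    candidates: dict[str, list[str]] = {}
    truth: dict[str, str] = {}
    decoy_counter = 0
    for mol in pool:
        n_near = (n_c - 1 + 1) // 2 if cfg.near_decoy_flip_bits > 0 else 0
        n_far = n_c - 1 - n_near
        clist = [mol]
        for _ in range(n_near):
            v = fps.bits[mol].copy()
            flip = rng.choice(fps.d, size=min(cfg.near_decoy_flip_bits, fps.d),
                              replace=False)
            v[flip] ^= 1
            decoy_counter += 1
            did = f"decoy{decoy_counter:05d}"
            out.add(did, v)
            clist.append(did)
        for _ in range(n_far):
            decoy_counter += 1
            did = f"decoy{decoy_counter:05d}"
            out.add(did, _draw_fp(cfg, rng, block_of))
            clist.append(did)
        order = rng.permutation(len(clist))
        candidates[mol] = [clist[i] for i in order]
        truth[mol] = mol
    return CandidateSets(candidates, truth), out


@dataclass
class SyntheticBenchmark:
    """A complete generated dataset: one spectrum list per view (identical
    molecule/query ids across views), the fingerprint table including decoys,
    candidate sets, and group labels (group = molecule)."""

    cfg: GeneratorConfig
    spectra_views: dict[str, list[Spectrum]] = field(default_factory=dict)
    fingerprints: FingerprintTable = None  # type: ignore[assignment]
    candidates: CandidateSets = None  # type: ignore[assignment]
    groups: dict[str, str] = field(default_factory=dict)

    @property
    def query_ids(self) -> list[str]:
        return list(self.candidates.candidates)


def generate_benchmark(cfg: GeneratorConfig) -> SyntheticBenchmark:
    """Generate the full benchmark from ``cfg.seed``.

    Every view draws its own fragment dictionary and per-spectrum noise, so
    views are conditionally independent given the molecules — the role that
    distinct input kernels play on real data. Query ids equal molecule ids;
    group ids equal molecule ids (one structure per molecule).
    """
    logger.info("generating synthetic benchmark (seed=%d)", cfg.seed)
    fps = sample_fingerprints(cfg, _child_rng(cfg.seed, 0))
    views: dict[str, list[Spectrum]] = {}
    for v in range(cfg.n_views):
        table = make_fragment_table(cfg, _child_rng(cfg.seed, 1, v))
        spectra = []
        for i, mol in enumerate(fps.ids):
            rng = _child_rng(cfg.seed, 2, v, i)
            spectra.append(
                spectrum_from_fingerprint(mol, mol, fps.bits[mol], table, cfg, rng)
            )
        views[f"view{v+1}"] = spectra
    cands, full_fps = make_candidate_sets(fps, cfg, _child_rng(cfg.seed, 3))
    groups = {mol: mol for mol in fps.ids}
    return SyntheticBenchmark(cfg, views, full_fps, cands, groups)
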