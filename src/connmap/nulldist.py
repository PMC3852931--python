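"""Monte-Carlo null distribution of connection scores and empirical p-values.

A random gene signature of length m is built from m uniform draws
u ~ U[0,1): with v = u*N, the integer part of v picks the gene (0-based
index into the universe order) and the fractional part picks the flag
(+1 below 0.5, -1 at or above).  One uniform therefore carries both gene
identity and direction, so a query needs exactly m * n_rdsigs live draws.
Sampling is with replacement; for the m << N regimes this engine targets
(m <= a few hundred vs N in the tens of thousands) duplicates are
vanishingly rare and the rule stays rejection-free and branchless.

Randomness comes from the counter-based Philox generator keyed by the run
seed.  Philox advances in 4x64-bit counter blocks, so each signature's
draws are aligned to a block boundary (stride = ceil(m/4)*4 uniforms per
signature, padding discarded).  Signature i always reads the same
positions of the keyed stream, which makes the null scores a pure
function of (inputs, n_rdsigs, seed): chunk size and evaluation order
cannot change them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from numpy.random import Generator, Philox

from .refdata import GeneSignature, GeneUniverse, RefSet
from .scoring import max_raw_strength, raws_from_summed, summed_rank_vector

logger = logging.getLogger("connmap")

DEFAULT_N_RDSIGS = 10_000
DEFAULT_EFP = 1.0
DEFAULT_REFSET_MODE = "by_drug_cell_dose"
DEFAULT_CHUNK_SIZE = 4096


@dataclass(frozen=True)
class RunConfig:
    """Run parameters for significance estimation.

    Results are a pure function of the inputs, ``n_rdsigs`` and ``seed``;
    ``chunk_size`` only sets execution granularity and never changes them.
    """

    seed: int
    n_rdsigs: int = DEFAULT_N_RDSIGS
    efp_tolerance: float = DEFAULT_EFP
    refset_mode: str = DEFAULT_REFSET_MODE
    chunk_size: int = DEFAULT_CHUNK_SIZE

    def __post_init__(self):
        if self.n_rdsigs < 100:
            raise ValueError("n_rdsigs must be at least 100")
        if self.n_rdsigs < 1000:
            logger.warning(
                "n_rdsigs=%d is low; p-value resolution is only %.3g",
                self.n_rdsigs,
                1.0 / (self.n_rdsigs + 1),
            )
        if self.efp_tolerance <= 0:
            raise ValueError("efp_tolerance must be positive")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be positive")


@dataclass(frozen=True)
class RandomScoreBatch:
    """Null refset scores for one (refset, m, seed) combination."""

    set_id: str
    scores: np.ndarray  # float64, shape (n_rdsigs,)
    m: int
    seed: int

    @property
    def n_rdsigs(self) -> int:
        return len(self.scores)


def draw_uniforms(count: int, seed: int) -> np.ndarray:
    """``count`` U[0,1) draws from the Philox stream keyed by ``seed``."""
    if count < 1:
        raise ValueError("count must be >= 1")
    return Generator(Philox(key=seed)).random(count)


def _signature_stride(m: int) -> int:
    # Philox.advance moves whole 4x64-bit blocks; pad each signature to one.
    return -(-m // 4) * 4


def _chunk_uniforms(seed: int, start: int, stop: int, m: int) -> np.ndarray:
    """U[0,1) draws for signatures [start, stop): shape (stop-start, m)."""
    stride = _signature_stride(m)
    bg = Philox(key=seed)
    bg.advance(start * stride // 4)
    u = Generator(bg).random((stop - start) * stride)
    return u.reshape(stop - start, stride)[:, :m]


def uniforms_to_indices(u: np.ndarray, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Map uniforms to (gene index, flag) pairs.

    v = u*N; index = floor(v); flag = +1 if the fractional part of v is
    below 0.5 else -1.  Works elementwise on arrays of any shape.
    """
    u = np.asarray(u, dtype=np.float64)
    if np.any((u < 0.0) | (u >= 1.0)):
        raise ValueError("uniform draws must lie in [0, 1)")
    v = u * N
    idx = np.floor(v).astype(np.int64)
    np.minimum(idx, N - 1, out=idx)  # guard the float round-up edge at u -> 1
    flags = np.where(v - idx < 0.5, 1, -1).astype(np.int64)
    return idx, flags


def uniforms_to_signature(
    u: Sequence[float], universe: GeneUniverse, signature_id: str = "random"
) -> GeneSignature:
    """Build a random GeneSignature of length len(u) from uniform draws."""
    idx, flags = uniforms_to_indices(np.atleast_1d(np.asarray(u)), universe.N)
    entries = tuple(
        (universe.gene_ids[int(i)], int(s)) for i, s in zip(idx, flags)
    )
    return GeneSignature(signature_id, entries)


def _chunk_bounds(n: int, chunk_size: int) -> Iterator[tuple[int, int]]:
    for start in range(0, n, chunk_size):
        yield start, min(start + chunk_size, n)


def null_score_matrix(
    refsets: Sequence[RefSet], m: int, config: RunConfig
) -> np.ndarray:
    """Null refset scores, one random-signature pool shared across refsets.

    Returns a (len(refsets), n_rdsigs) float64 matrix: row r holds the
    scores of refset r against the same n_rdsigs random signatures of
    length m.  Sharing one pool per query matches the engine's draw budget
    of m * n_rdsigs uniforms per query.  Computation is chunked over the
    signature index; the result is invariant to chunk_size.
    """
    if not refsets:
        return np.empty((0, config.n_rdsigs))
    universe = refsets[0].universe
    N = universe.N
    if not 1 <= m <= N:
        raise ValueError(f"need 1 <= m <= N, got m={m}, N={N}")
    maxsum = max_raw_strength(m, N)
    summed = [summed_rank_vector(rs.rank_matrix()) for rs in refsets]
    out = np.empty((len(refsets), config.n_rdsigs))
    for start, stop in _chunk_bounds(config.n_rdsigs, config.chunk_size):
        u = _chunk_uniforms(config.seed, start, stop, m)
        idx, flags = uniforms_to_indices(u, N)
        for r, (rs, sranks) in enumerate(zip(refsets, summed)):
            raws = raws_from_summed(sranks, idx, flags)
            out[r, start:stop] = raws / (rs.K * maxsum)
    return out


def random_scores(refset: RefSet, m: int, config: RunConfig) -> RandomScoreBatch:
    """Null score distribution of one refset against random length-m signatures."""
    scores = null_score_matrix([refset], m, config)[0]
    return RandomScoreBatch(refset.set_id, scores, m=m, seed=config.seed)


def empirical_pvalue(observed: float, batch: RandomScoreBatch | np.ndarray) -> float:
    """Two-sided empirical p-value with the add-one (never-zero) correction.

    p = (#{ random |r| >= |observed| } + 1) / (n_rdsigs + 1), in (0, 1].
    """
    scores = batch.scores if isinstance(batch, RandomScoreBatch) else np.asarray(batch)
    if scores.size == 0:
        raise ValueError("empty random-score batch")
    count = int(np.count_nonzero(np.abs(scores) >= abs(observed)))
    return (count + 1) / (scores.size + 1)


def empirical_pvalues(observed: np.ndarray, score_matrix: np.ndarray) -> np.ndarray:
    """Row-wise empirical p-values for many refsets at once."""
    observed = np.asarray(observed, dtype=np.float64)
    if score_matrix.shape[0] != observed.shape[0]:
        raise ValueError("one observed score per score-matrix row is required")
    n = score_matrix.shape[1]
    counts = np.count_nonzero(
        np.abs(score_matrix) >= np.abs(observed)[:, None], axis=1
    )
    return (counts + 1) / (n + 1)
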