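"""The signed-rank connection score between a query signature and a refset.

For a profile with signed ranks R(g) and a signature of m genes with flags
s(g) in {+1, -1}, the raw connection strength is the integer

    raw = sum over signature genes of R(g) * s(g)

normalized by the largest value raw can take over any m distinct genes,
the top-m rank-magnitude sum

    maxsum(m, N) = N + (N-1) + ... + (N-m+1) = m*N - m*(m-1)/2 .

The per-profile score raw / maxsum lies in [-1, 1]: +1 when the signature
genes are exactly the m most extreme genes with every flag matching the
rank sign (perfect mimicry), -1 for the fully reversed case.  A refset's
score is the arithmetic mean of its members' scores; since all members
share maxsum this equals (sum of member raws) / (K * maxsum), computed as
exact integer sums followed by one double-precision division, so batched
and scalar evaluation agree bit for bit.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .refdata import GeneSignature, RefSet, ReferenceProfile


def max_raw_strength(m: int, N: int) -> int:
    """Largest achievable raw strength over m distinct genes of an N-gene profile."""
    if not 1 <= m <= N:
        raise ValueError(f"need 1 <= m <= N, got m={m}, N={N}")
    return m * N - m * (m - 1) // 2


def raw_strength(profile: ReferenceProfile, signature: GeneSignature) -> int:
    """Exact integer sum of signed-rank x flag products."""
    total = 0
    for gene, flag in signature.entries:
        idx = profile.universe.index.get(gene)
        if idx is None:
            raise KeyError(f"signature gene {gene!r} not in profile universe")
        total += int(profile.ranks[idx]) * flag
    return total


def connection_strength(profile: ReferenceProfile, signature: GeneSignature) -> float:
    """Normalized per-profile connection score in [-1, 1]."""
    return raw_strength(profile, signature) / max_raw_strength(
        signature.m, profile.universe.N
    )


def refset_score(refset: RefSet, signature: GeneSignature) -> float:
    """Mean member score: (sum of integer raw strengths) / (K * maxsum)."""
    total = sum(raw_strength(p, signature) for p in refset.members)
    return total / (refset.K * max_raw_strength(signature.m, refset.universe.N))


def summed_rank_vector(rank_matrix: np.ndarray) -> np.ndarray:
    """(N,) int64 member-summed ranks of a refset's (K, N) rank matrix."""
    return rank_matrix.sum(axis=0, dtype=np.int64)


def raws_from_summed(
    summed_ranks: np.ndarray, gene_idx: np.ndarray, flags: np.ndarray
) -> np.ndarray:
    """Member-summed raw strengths of many signatures against one refset.

    Exploits linearity: sum_k sum_g R_k(g) s(g) = sum_g s(g) * (sum_k R_k)(g),
    so one (N,) summed-rank vector serves the whole refset.  gene_idx and
    flags are (n_sigs, m) int64 arrays; returns (n_sigs,) int64 raw sums
    (divide by K * maxsum for refset scores).  Duplicate gene indices within
    a signature are legal and simply contribute twice, as in the scalar
    definition.
    """
    return np.einsum("sm,sm->s", summed_ranks[gene_idx], flags, dtype=np.int64)


def batch_refset_raws(
    rank_matrix: np.ndarray, gene_idx: np.ndarray, flags: np.ndarray
) -> np.ndarray:
    """Summed raw strengths of one refset against many signatures at once."""
    return raws_from_summed(summed_rank_vector(rank_matrix), gene_idx, flags)


def score_all(
    refsets: Sequence[RefSet], signature: GeneSignature
) -> list[tuple[str, float]]:
    """Score one signature against every refset, batched over the rank arrays.

    Agrees exactly with per-profile scalar evaluation: raw strengths are
    exact integer sums and the single division happens once per refset.
    """
    if not refsets:
        return []
    universe = refsets[0].universe
    gene_idx = signature.gene_indices(universe)[None, :]
    flags = signature.flags()[None, :]
    maxsum = max_raw_strength(signature.m, universe.N)
    out = []
    for rs in refsets:
        raw = int(batch_refset_raws(rs.rank_matrix(), gene_idx, flags)[0])
        out.append((rs.set_id, raw / (rs.K * maxsum)))
    return out
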