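"""Synthetic reference databases and query signatures for desk-scale testing.

The generator emulates the structure of a connectivity-mapping reference
database — signed-permutation rank profiles over an N-gene universe, with
filenames encoding drug / cell line / dose — without any real expression
data.  Null profiles have i.i.d. +/-1 signs and uniformly random rank
magnitudes; planted refsets place a chosen fraction of a query signature's
genes into the top rank slots with matching signs, giving positive
controls of known strength (theta = 1 scores exactly +1.0, theta = 0
reduces to the null model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

from .refdata import (
    GeneSignature,
    GeneUniverse,
    RefSet,
    ReferenceProfile,
)


def _as_rng(seed) -> Generator:
    return seed if isinstance(seed, Generator) else default_rng(seed)


def generate_universe(N: int, seed) -> GeneUniverse:
    """N unique probeset-style identifiers (e.g. '213705_at'), seed-deterministic."""
    if N < 2:
        raise ValueError("universe needs N >= 2 genes")
    rng = _as_rng(seed)
    nums = rng.choice(900_000, size=N, replace=False) + 100_000
    return GeneUniverse(tuple(f"{n}_at" for n in nums))


def generate_null_profile(
    universe: GeneUniverse,
    seed,
    profile_id: str = "null",
    drug: str = "",
    cell: str = "",
    dose: str = "",
) -> ReferenceProfile:
    """Null model: magnitudes a uniform random permutation of 1..N, signs i.i.d. +/-1."""
    rng = _as_rng(seed)
    N = universe.N
    mags = rng.permutation(N) + 1
    signs = rng.integers(0, 2, size=N) * 2 - 1
    return ReferenceProfile(
        profile_id, universe, mags * signs, drug=drug, cell=cell, dose=dose
    )


def generate_random_signature(
    universe: GeneUniverse, m: int, seed, signature_id: str = "random"
) -> GeneSignature:
    """A user-style signature: m distinct genes, flags i.i.d. +/-1."""
    if not 1 <= m <= universe.N:
        raise ValueError(f"need 1 <= m <= N, got m={m}, N={universe.N}")
    rng = _as_rng(seed)
    idx = rng.choice(universe.N, size=m, replace=False)
    flags = rng.integers(0, 2, size=m) * 2 - 1
    entries = tuple(
        (universe.gene_ids[int(i)], int(s)) for i, s in zip(idx, flags)
    )
    return GeneSignature(signature_id, entries)


def generate_planted_profile(
    universe: GeneUniverse,
    signature: GeneSignature,
    theta: float,
    seed,
    profile_id: str = "planted",
    drug: str = "",
    cell: str = "",
    dose: str = "",
) -> ReferenceProfile:
    """One profile with round(theta*m) signature genes planted in the top rank slots.

    The planted genes (a random subset of the signature) receive the
    magnitudes N, N-1, ..., with sign equal to their signature flag; every
    other gene — including the un-planted signature genes — is filled from
    the null model.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    rng = _as_rng(seed)
    N, m = universe.N, signature.m
    sig_idx = signature.gene_indices(universe)
    if len(set(sig_idx.tolist())) != m:
        raise ValueError("planted signatures must have distinct genes")
    flags = signature.flags()
    n_planted = int(math.floor(theta * m + 0.5))

    chosen = rng.permutation(m)[:n_planted]
    planted_idx = sig_idx[chosen]
    ranks = np.zeros(N, dtype=np.int64)
    top_mags = rng.permutation(np.arange(N - n_planted + 1, N + 1))
    ranks[planted_idx] = top_mags * flags[chosen]

    rest = np.setdiff1d(np.arange(N), planted_idx)
    rest_mags = rng.permutation(np.arange(1, N - n_planted + 1))
    rest_signs = rng.integers(0, 2, size=N - n_planted) * 2 - 1
    ranks[rest] = rest_mags * rest_signs
    return ReferenceProfile(
        profile_id, universe, ranks, drug=drug, cell=cell, dose=dose
    )


def generate_profile_with_score(
    universe: GeneUniverse,
    signature: GeneSignature,
    score: float,
    seed,
    profile_id: str = "scored",
) -> ReferenceProfile:
    """A profile whose connection strength against ``signature`` is fixed.

    The signature's genes receive distinct rank magnitudes summing to
    round(score * maxsum), each with sign equal to its flag, so the raw
    strength — and hence the score, up to the 1/maxsum integer grid — is
    deterministic regardless of ``seed``.  All other genes are null-filled
    and never touch the observed score.  Useful for placing an observed
    score at a chosen quantile of the null distribution.
    """
    if not 0.0 < score <= 1.0:
        raise ValueError("score must lie in (0, 1]")
    rng = _as_rng(seed)
    N, m = universe.N, signature.m
    maxsum = m * N - m * (m - 1) // 2
    t = round(score * maxsum)
    if t < m * (m + 1) // 2:
        raise ValueError(f"score {score} unreachable with m={m} distinct magnitudes")
    # m consecutive magnitudes near t/m, remainder added to the largest
    base = (t - m * (m - 1) // 2) // m
    mags = np.arange(base, base + m)
    mags[-1] += t - int(mags.sum())
    if mags[-1] > N:
        raise ValueError(f"score {score} unreachable within magnitudes 1..{N}")
    sig_idx = signature.gene_indices(universe)
    ranks = np.zeros(N, dtype=np.int64)
    ranks[sig_idx] = mags * signature.flags()
    rest = np.setdiff1d(np.arange(N), sig_idx)
    rest_mags = rng.permutation(np.setdiff1d(np.arange(1, N + 1), mags))
    rest_signs = rng.integers(0, 2, size=rest.size) * 2 - 1
    ranks[rest] = rest_mags * rest_signs
    return ReferenceProfile(profile_id, universe, ranks)


def generate_planted_refset(
    universe: GeneUniverse,
    signature: GeneSignature,
    theta: float,
    K: int,
    seed,
    set_id: str = "planted",
) -> RefSet:
    """K planted member profiles sharing one (signature, theta) positive control."""
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = _as_rng(seed)
    members = tuple(
        generate_planted_profile(
            universe, signature, theta, rng, profile_id=f"{set_id}_{k:02d}"
        )
        for k in range(K)
    )
    return RefSet(set_id, members)


# ---------------------------------------------------------------------------
# on-disk fixture trees


@dataclass(frozen=True)
class FixtureManifest:
    """Exact description of a synthetic fixture tree.

    ``profiles`` holds (filename, drug, cell, dose) grouping truth;
    ``queries`` holds (query_id, m); ``planted`` holds
    (query_id, set_id, theta) positive controls, where set_id is the
    drug_cell_dose key of the refset whose members carry the plant.
    """

    N: int
    profiles: tuple[tuple[str, str, str, str], ...]
    queries: tuple[tuple[str, int], ...] = ()
    planted: tuple[tuple[str, str, float], ...] = ()

    @property
    def n_profiles(self) -> int:
        return len(self.profiles)


def standard_manifest(
    N: int = 1000,
    n_profiles: int = 50,
    query_lengths: Sequence[int] = (10, 25, 189),
    planted: Sequence[tuple[str, str, float]] = (),
    n_drugs: int = 10,
) -> FixtureManifest:
    """The desk-scale test tree: N genes, replicated drug/cell/dose profiles,
    and one query per requested signature length."""
    cells = ("MCF7", "PC3")
    profiles = []
    for j in range(n_profiles):
        drug = f"drug{j % n_drugs:02d}"
        cell = cells[(j // n_drugs) % len(cells)]
        dose = "1e-6"
        profiles.append((f"{drug}_{cell}_{dose}_{j:03d}.tab", drug, cell, dose))
    queries = tuple((f"sig{m:03d}", m) for m in query_lengths)
    return FixtureManifest(
        N=N, profiles=tuple(profiles), queries=queries, planted=tuple(planted)
    )


def write_signature_file(path: Path, signature: GeneSignature) -> None:
    lines = [f"{g}\t{'+1' if s > 0 else '-1'}" for g, s in signature.entries]
    Path(path).write_text("\n".join(lines) + "\n")


def write_profile_file(path: Path, profile: ReferenceProfile) -> None:
    lines = [
        f"{g}\t{int(r)}" for g, r in zip(profile.universe.gene_ids, profile.ranks)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixture_tree(
    out_dir: Path, manifest: FixtureManifest, seed: int, overwrite: bool = False
) -> dict:
    """Materialise a manifest as ref-files/ + queries/ + manifest.tsv.

    Returns {'universe': GeneUniverse, 'signatures': {query_id: GeneSignature}}
    so tests can compare loaded data against what was written.  All content
    is a pure function of (manifest, seed).
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{out_dir} exists and is not empty (pass overwrite=True to replace)"
            )
    ref_dir = out_dir / "ref-files"
    query_dir = out_dir / "queries"
    ref_dir.mkdir(parents=True, exist_ok=True)
    query_dir.mkdir(parents=True, exist_ok=True)

    nq, npf = len(manifest.queries), manifest.n_profiles
    seeds = SeedSequence(seed).generate_state(1 + nq + npf)
    universe = generate_universe(manifest.N, int(seeds[0]))

    signatures: dict[str, GeneSignature] = {}
    for i, (query_id, m) in enumerate(manifest.queries):
        sig = generate_random_signature(
            universe, m, int(seeds[1 + i]), signature_id=query_id
        )
        signatures[query_id] = sig
        write_signature_file(query_dir / f"{query_id}.tab", sig)

    plant_by_set = {set_id: (query_id, theta) for query_id, set_id, theta in manifest.planted}
    for j, (filename, drug, cell, dose) in enumerate(manifest.profiles):
        set_key = "_".join((drug, cell, dose))
        pseed = int(seeds[1 + nq + j])
        if set_key in plant_by_set:
            query_id, theta = plant_by_set[set_key]
            profile = generate_planted_profile(
                universe,
                signatures[query_id],
                theta,
                pseed,
                profile_id=Path(filename).stem,
                drug=drug,
                cell=cell,
                dose=dose,
            )
        else:
            profile = generate_null_profile(
                universe,
                pseed,
                profile_id=Path(filename).stem,
                drug=drug,
                cell=cell,
                dose=dose,
            )
        write_profile_file(ref_dir / filename, profile)

    manifest_lines = ["filename\tdrug\tcell\tdose"]
    manifest_lines += [
        "\t".join(row) for row in manifest.profiles
    ]
    (out_dir / "manifest.tsv").write_text("\n".join(manifest_lines) + "\n")
    return {"universe": universe, "signatures": signatures}
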