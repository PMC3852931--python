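"""Reading, validating and grouping signed-rank reference databases and query signatures.

The on-disk layout mirrors the classic connectivity-mapping tools: a
``ref-files`` directory with one tab-delimited file per drug-treated
instance (``gene_id<TAB>signed_rank``, one line per gene in the universe),
and a ``queries`` directory with one file per query signature
(``gene_id<TAB>flag`` with flag +1/-1).

A reference profile assigns every gene in the universe a signed rank: the
sign is the direction of differential regulation and the magnitude the
strength, with magnitude ``N`` the most extreme gene.  The magnitudes of a
valid profile are exactly the permutation ``1..N``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("connmap")

REFSET_MODES = ("by_drug", "by_drug_cell_dose")

#: name of the optional metadata sidecar inside a ref-files directory
METADATA_SIDECAR = "metadata.tsv"


class RefDataError(ValueError):
    """Fatal validation error in reference or query data."""


@dataclass(frozen=True)
class GeneUniverse:
    """The ordered list of gene identifiers shared by every reference profile."""

    gene_ids: tuple[str, ...]
    index: Mapping[str, int] = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if len(self.gene_ids) < 2:
            raise RefDataError("gene universe needs at least 2 genes")
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        if len(idx) != len(self.gene_ids):
            raise RefDataError("gene universe contains duplicate identifiers")
        object.__setattr__(self, "index", idx)

    @property
    def N(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.index

    def __len__(self) -> int:
        return self.N


@dataclass(frozen=True)
class ReferenceProfile:
    """One drug-treated instance: a signed rank for every universe gene.

    ``ranks`` is stored as an int64 array aligned with the universe order;
    ``ranks[i]`` is the signed rank of ``universe.gene_ids[i]``.
    """

    profile_id: str
    universe: GeneUniverse
    ranks: np.ndarray  # int64, shape (N,)
    drug: str = ""
    cell: str = ""
    dose: str = ""

    def __post_init__(self):
        r = np.asarray(self.ranks, dtype=np.int64)
        if r.shape != (self.universe.N,):
            raise RefDataError(
                f"profile {self.profile_id!r}: expected {self.universe.N} ranks, "
                f"got shape {r.shape}"
            )
        validate_signed_permutation(r, self.profile_id)
        object.__setattr__(self, "ranks", r)

    def rank_of(self, gene_id: str) -> int:
        """Signed rank of one gene (raises KeyError for genes outside the universe)."""
        return int(self.ranks[self.universe.index[gene_id]])


def validate_signed_permutation(ranks: np.ndarray, profile_id: str = "?") -> None:
    """Check that the rank magnitudes are exactly the permutation 1..N."""
    mags = np.abs(ranks)
    N = ranks.shape[0]
    counts = np.bincount(mags, minlength=N + 1)
    if counts[0] > 0:
        raise RefDataError(f"profile {profile_id!r}: rank magnitude 0 is not allowed")
    bad = np.nonzero(counts[1 : N + 1] != 1)[0]
    if bad.size:
        mag = int(bad[0]) + 1
        word = "absent" if counts[mag] == 0 else f"seen {counts[mag]} times"
        raise RefDataError(
            f"profile {profile_id!r}: magnitudes are not a permutation of 1..{N} "
            f"(magnitude {mag} {word})"
        )


@dataclass(frozen=True)
class RefSet:
    """A named group of reference profiles scored as a unit."""

    set_id: str
    members: tuple[ReferenceProfile, ...]

    def __post_init__(self):
        if not self.members:
            raise RefDataError(f"refset {self.set_id!r} has no members")
        u = self.members[0].universe
        if any(p.universe is not u and p.universe != u for p in self.members):
            raise RefDataError(f"refset {self.set_id!r} mixes gene universes")

    @property
    def K(self) -> int:
        return len(self.members)

    @property
    def universe(self) -> GeneUniverse:
        return self.members[0].universe

    def rank_matrix(self) -> np.ndarray:
        """(K, N) int64 matrix of member signed ranks, universe order."""
        return np.stack([p.ranks for p in self.members])


@dataclass(frozen=True)
class GeneSignature:
    """A short list of genes each flagged up (+1) or down (-1).

    User-supplied signatures have unique genes (enforced at load time);
    randomly generated signatures may repeat a gene, which this container
    permits.
    """

    signature_id: str
    entries: tuple[tuple[str, int], ...]

    def __post_init__(self):
        if not self.entries:
            raise RefDataError(f"signature {self.signature_id!r} is empty")
        if any(flag not in (1, -1) for _, flag in self.entries):
            raise RefDataError(f"signature {self.signature_id!r}: flags must be +1/-1")

    @property
    def m(self) -> int:
        return len(self.entries)

    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.entries)

    def flags(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=np.int64)

    def gene_indices(self, universe: GeneUniverse) -> np.ndarray:
        return np.array([universe.index[g] for g, _ in self.entries], dtype=np.int64)

    def flipped(self) -> "GeneSignature":
        """Same genes with all flags reversed."""
        return GeneSignature(
            self.signature_id + "_flipped",
            tuple((g, -s) for g, s in self.entries),
        )


# ---------------------------------------------------------------------------
# file loading


def _reference_files(ref_dir: Path) -> list[Path]:
    files = sorted(
        p
        for p in Path(ref_dir).iterdir()
        if p.is_file() and p.name != METADATA_SIDECAR and not p.name.startswith(".")
    )
    return files


def parse_profile_filename(filename: str) -> tuple[str, str, str]:
    """Parse ``drug_cell_dose_replicate.ext`` metadata out of a filename.

    Tokens are assigned right to left (replicate, dose, cell); everything
    left over is the drug, so drug names may themselves contain underscores.
    Missing trailing tokens yield empty fields.
    """
    stem = Path(filename).stem
    tokens = stem.split("_")
    if len(tokens) >= 4:
        return "_".join(tokens[:-3]), tokens[-3], tokens[-2]
    if len(tokens) == 3:
        return tokens[0], "", tokens[1]
    return tokens[0], "", ""


def read_metadata_sidecar(ref_dir: Path) -> dict[str, tuple[str, str, str]]:
    """Read the optional metadata TSV (header: filename drug cell dose)."""
    path = Path(ref_dir) / METADATA_SIDECAR
    meta: dict[str, tuple[str, str, str]] = {}
    if not path.exists():
        return meta
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"filename", "drug", "cell", "dose"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise RefDataError(
                f"{path}: metadata sidecar must have columns filename/drug/cell/dose"
            )
        for row in reader:
            meta[row["filename"]] = (row["drug"], row["cell"], row["dose"])
    return meta


def load_universe(ref_dir: Path) -> GeneUniverse:
    """Take the gene universe from the first reference file (lexicographic order).

    The universe ordering is the line order of that file; every other file
    must match it exactly (checked when each profile is loaded).
    """
    files = _reference_files(Path(ref_dir))
    if not files:
        raise RefDataError(f"no reference files found in {ref_dir}")
    first = files[0]
    gene_ids: list[str] = []
    try:
        with first.open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise RefDataError(
                        f"{first}:{lineno}: expected 'gene_id<TAB>signed_rank'"
                    )
                gene_ids.append(parts[0])
    except OSError as exc:
        raise RefDataError(f"cannot read reference file {first}: {exc}") from exc
    return GeneUniverse(tuple(gene_ids))


def load_reference_profile(
    path: Path,
    universe: GeneUniverse,
    metadata: Mapping[str, tuple[str, str, str]] | None = None,
) -> ReferenceProfile:
    """Load and validate one two-column reference file against the universe."""
    path = Path(path)
    profile_id = path.stem
    ranks = np.zeros(universe.N, dtype=np.int64)
    seen = np.zeros(universe.N, dtype=bool)
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise RefDataError(f"{path}:{lineno}: expected 'gene_id<TAB>signed_rank'")
            gene, rank_str = parts
            idx = universe.index.get(gene)
            if idx is None:
                raise RefDataError(f"{path}:{lineno}: gene {gene!r} not in universe")
            if seen[idx]:
                raise RefDataError(f"{path}:{lineno}: duplicate gene {gene!r}")
            try:
                rank = int(rank_str)
            except ValueError:
                raise RefDataError(
                    f"{path}:{lineno}: rank {rank_str!r} is not an integer"
                ) from None
            seen[idx] = True
            ranks[idx] = rank
    if not seen.all():
        missing = universe.gene_ids[int(np.flatnonzero(~seen)[0])]
        raise RefDataError(f"{path}: gene {missing!r} missing from profile")
    if metadata and path.name in metadata:
        drug, cell, dose = metadata[path.name]
    else:
        drug, cell, dose = parse_profile_filename(path.name)
    return ReferenceProfile(profile_id, universe, ranks, drug=drug, cell=cell, dose=dose)


def load_reference_database(
    ref_dir: Path, universe: GeneUniverse | None = None
) -> tuple[GeneUniverse, list[ReferenceProfile]]:
    """Load every profile in ``ref_dir`` against a common universe."""
    ref_dir = Path(ref_dir)
    if universe is None:
        universe = load_universe(ref_dir)
    metadata = read_metadata_sidecar(ref_dir)
    profiles = [
        load_reference_profile(p, universe, metadata) for p in _reference_files(ref_dir)
    ]
    return universe, profiles


def group_refsets(
    profiles: Sequence[ReferenceProfile], mode: str = "by_drug_cell_dose"
) -> list[RefSet]:
    """Partition profiles into refsets keyed by drug, or by (drug, cell, dose).

    Set ids join the key with underscores; the result is ordered
    lexicographically by set id so runs are deterministic.
    """
    if mode not in REFSET_MODES:
        raise RefDataError(f"unknown refset mode {mode!r}; use one of {REFSET_MODES}")
    groups: dict[str, list[ReferenceProfile]] = {}
    for p in profiles:
        key = p.drug if mode == "by_drug" else "_".join((p.drug, p.cell, p.dose))
        groups.setdefault(key, []).append(p)
    return [RefSet(set_id, tuple(members)) for set_id, members in sorted(groups.items())]


_FLAG_SPELLINGS = {"1": 1, "+1": 1, "-1": -1}


def load_signature(path: Path, universe: GeneUniverse) -> GeneSignature:
    """Load a two-column query signature, dropping genes outside the universe.

    Dropped genes are logged as warnings; a signature left empty after
    filtering, a duplicate gene, or an unparseable flag is fatal.
    """
    path = Path(path)
    entries: list[tuple[str, int]] = []
    seen: set[str] = set()
    dropped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise RefDataError(f"{path}:{lineno}: expected 'gene_id<TAB>flag'")
            gene, flag_str = parts
            flag = _FLAG_SPELLINGS.get(flag_str.strip())
            if flag is None:
                raise RefDataError(f"{path}:{lineno}: unparseable flag {flag_str!r}")
            if gene in seen:
                raise RefDataError(f"{path}:{lineno}: duplicate gene {gene!r}")
            seen.add(gene)
            if gene not in universe:
                logger.warning("%s:%d: gene %r not in universe, dropped", path, lineno, gene)
                dropped += 1
                continue
            entries.append((gene, flag))
    if not entries:
        raise RefDataError(
            f"{path}: no signature genes remain after filtering against the universe"
        )
    if dropped:
        logger.warning("%s: dropped %d/%d genes outside the universe", path, dropped, dropped + len(entries))
    return GeneSignature(path.stem, tuple(entries))


def load_queries(query_dir: Path, universe: GeneUniverse) -> list[GeneSignature]:
    """Load every query signature file in lexicographic order."""
    query_dir = Path(query_dir)
    files = sorted(
        p for p in query_dir.iterdir() if p.is_file() and not p.name.startswith(".")
    )
    if not files:
        raise RefDataError(f"no query files found in {query_dir}")
    return [load_signature(p, universe) for p in files]
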