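"""Significance calls under an expected-false-positives tolerance, and results output.

With M refsets tested per query and a tolerated expected number of false
positives T, each refset is called significant when its empirical p-value
is at or below the per-test threshold alpha = T / M.  Under the null this
controls E[false positives per query] at (approximately, up to the
discreteness of the Monte-Carlo p-value lattice) T.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence


@dataclass(frozen=True)
class ConnectionResult:
    """One (query, refset) connection with its significance call."""

    query_id: str
    set_id: str
    K: int
    score: float
    pvalue: float
    threshold: float
    significant: bool
    direction: str  # "positive", "negative", or "" for a zero score


def efp_threshold(T: float, M: int) -> float:
    """Per-refset p-value threshold tolerating T expected false positives over M tests."""
    if M < 1:
        raise ValueError("M (number of refsets tested) must be >= 1")
    if T <= 0:
        raise ValueError("expected-false-positives tolerance T must be positive")
    return T / M


def assemble_results(
    query_id: str,
    scored: Sequence[tuple[str, int, float, float]],
    threshold: float,
) -> list[ConnectionResult]:
    """Rank (set_id, K, score, pvalue) entries and set significance flags.

    Sorted by ascending p-value, ties broken by descending |score|, then
    lexicographic set id.
    """
    results = [
        ConnectionResult(
            query_id=query_id,
            set_id=set_id,
            K=K,
            score=score,
            pvalue=pvalue,
            threshold=threshold,
            significant=pvalue <= threshold,
            direction="positive" if score > 0 else ("negative" if score < 0 else ""),
        )
        for set_id, K, score, pvalue in scored
    ]
    results.sort(key=lambda r: (r.pvalue, -abs(r.score), r.set_id))
    return results


RESULTS_HEADER = (
    "query_id",
    "set_id",
    "set_size",
    "connection_score",
    "p_value",
    "threshold",
    "significant",
)


def write_results(results: Sequence[ConnectionResult], out_path: Path) -> Path:
    """Write one query's ranked results as TSV.

    Scores carry 6 decimal places; p-values (and the threshold) use
    scientific notation with 4 significant digits.
    """
    out_path = Path(out_path)
    lines = ["\t".join(RESULTS_HEADER)]
    for r in results:
        lines.append(
            "\t".join(
                (
                    r.query_id,
                    r.set_id,
                    str(r.K),
                    f"{r.score:.6f}",
                    f"{r.pvalue:.3e}",
                    f"{r.threshold:.3e}",
                    "yes" if r.significant else "no",
                )
            )
        )
    try:
        out_path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write results file {out_path}: {exc}") from exc
    return out_path


def read_results(path: Path) -> list[ConnectionResult]:
    """Parse a results TSV back into ConnectionResult records (round-trip aid)."""
    lines = Path(path).read_text().splitlines()
    if not lines or tuple(lines[0].split("\t")) != RESULTS_HEADER:
        raise ValueError(f"{path}: not a connmap results file")
    out = []
    for line in lines[1:]:
        query_id, set_id, k, score, pvalue, threshold, sig = line.split("\t")
        score_f = float(score)
        out.append(
            ConnectionResult(
                query_id=query_id,
                set_id=set_id,
                K=int(k),
                score=score_f,
                pvalue=float(pvalue),
                threshold=float(threshold),
                significant=sig == "yes",
                direction="positive" if score_f > 0 else ("negative" if score_f < 0 else ""),
            )
        )
    return out
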