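"""Greedy prevalence-ordered clean-up of a barcode count table.

After excluding barcodes that are too rare to evaluate (< 100 lane-total
reads) or that contain 'N', barcodes are processed from most to least
prevalent.  Each barcode in turn acts as a potential mother and is compared
to every remaining less-prevalent barcode; candidates that satisfy all three
criteria (d_L <= 4, r <= 0.05, log-likelihood score above the threshold
line) are removed as daughters and never considered again.  Reads of
retained barcodes are left untouched: spurious reads are removed, not merged
into the mother.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .distance import levenshtein
from .model import CleanupParams, PairScore, loglik_score
from .tables import ReadCountTable

__all__ = [
    "PairEvaluation",
    "CleanupResult",
    "prefilter",
    "evaluate_pair",
    "clean_lane",
    "read_threshold_filter",
]

logger = logging.getLogger(__name__)

#: prefilter reasons
LOW_READS = "low-reads"
CONTAINS_N = "contains-N"


@dataclass(frozen=True)
class PairEvaluation:
    """Outcome of testing one (mother, daughter) candidate pair.

    ``verdict`` is "daughter" iff the distance, ratio and score criteria all
    pass; otherwise ``reason`` names the first failing criterion (distance,
    then ratio, then score).  ``score`` is None when the pair was rejected on
    distance alone (criteria are evaluated cheapest-first).
    """

    mother: str
    daughter: str
    distance: int
    score: PairScore | None
    verdict: str
    reason: str | None


@dataclass
class CleanupResult:
    """Partition of a table's barcodes into retained / removed classes."""

    retained: list[str]
    removed_as_daughter: list[PairEvaluation]
    removed_by_prefilter: list[tuple[str, str]]
    params: CleanupParams
    rescued: list[str] = field(default_factory=list)

    @property
    def removed_daughter_sequences(self) -> list[str]:
        return [ev.daughter for ev in self.removed_as_daughter]

    def all_barcodes(self) -> set[str]:
        return (
            set(self.retained)
            | set(self.removed_daughter_sequences)
            | {b for b, _ in self.removed_by_prefilter}
        )


def prefilter(
    table: ReadCountTable, params: CleanupParams = CleanupParams()
) -> tuple[ReadCountTable, list[tuple[str, str]]]:
    """Drop barcodes below the lane-total read cutoff or containing N.

    Returns the kept table and a list of (barcode, reason) for the removals.
    A barcode failing both tests is reported once, with the low-reads reason.
    """
    totals = table.totals()
    removed: list[tuple[str, str]] = []
    keep: list[str] = []
    for barcode, total in totals.items():
        if total < params.min_total_reads:
            removed.append((barcode, LOW_READS))
        elif set(barcode) - set("ACGT"):
            removed.append((barcode, CONTAINS_N))
        else:
            keep.append(barcode)
    return table.subset_barcodes(keep), removed


def evaluate_pair(
    mother_counts: Sequence[int],
    daughter_counts: Sequence[int],
    mother_seq: str,
    daughter_seq: str,
    params: CleanupParams = CleanupParams(),
) -> PairEvaluation:
    """Apply the three mother-daughter criteria to one ordered pair.

    The caller must pass the more prevalent barcode as the mother.
    """
    m = np.asarray(mother_counts, dtype=np.int64)
    c = np.asarray(daughter_counts, dtype=np.int64)
    if c.sum() > m.sum():
        raise ValueError(
            "mother must be at least as prevalent as the daughter "
            f"({int(m.sum())} < {int(c.sum())} reads)"
        )
    dist = levenshtein(mother_seq, daughter_seq)
    if dist > params.max_dist:
        return PairEvaluation(
            mother=mother_seq, daughter=daughter_seq, distance=dist,
            score=None, verdict="not-daughter", reason="distance",
        )
    score = loglik_score(c, m, params)
    if score.ratio > params.max_ratio:
        reason = "ratio"
    elif score.loglik is None:
        reason = "score-undefined"
    elif score.loglik <= score.threshold:
        reason = "score-below-threshold"
    else:
        reason = None
    return PairEvaluation(
        mother=mother_seq, daughter=daughter_seq, distance=dist, score=score,
        verdict="daughter" if reason is None else "not-daughter",
        reason=reason,
    )


def clean_lane(
    table: ReadCountTable,
    params: CleanupParams = CleanupParams(),
    keep_all_evaluations: bool = False,
) -> CleanupResult:
    """Run the full greedy clean-up on one lane's count table.

    Barcodes are sorted by lane-total reads (descending; ties broken
    lexicographically on the sequence, which makes the procedure
    deterministic and independent of input row order).  The most prevalent
    unprocessed barcode is fixed as a potential mother and compared against
    every remaining less-prevalent barcode; verdict-daughter barcodes are
    removed from further consideration.  Barcodes removed as daughters are
    never themselves considered as mothers.
    """
    if len(table.lane_ids) > 1:
        raise ValueError(
            f"clean_lane expects samples from a single lane, got {table.lane_ids}"
        )
    t0 = time.perf_counter()
    kept, prefiltered = prefilter(table, params)

    totals = kept.totals().to_numpy()
    barcodes = np.array(kept.barcodes, dtype=object)
    order = np.lexsort((barcodes, -totals))
    seqs = [str(b) for b in barcodes[order]]
    counts = kept.matrix()[order]

    n = len(seqs)
    active = np.ones(n, dtype=bool)
    removed: list[PairEvaluation] = []
    evaluations: list[PairEvaluation] = []
    for i in range(n):
        if not active[i]:
            continue
        for j in range(i + 1, n):
            if not active[j]:
                continue
            ev = evaluate_pair(counts[i], counts[j], seqs[i], seqs[j], params)
            if keep_all_evaluations:
                evaluations.append(ev)
            if ev.verdict == "daughter":
                active[j] = False
                removed.append(ev)

    retained = [seqs[i] for i in range(n) if active[i]]
    result = CleanupResult(
        retained=retained,
        removed_as_daughter=removed,
        removed_by_prefilter=prefiltered,
        params=params,
    )
    if keep_all_evaluations:
        result.evaluations = evaluations  # type: ignore[attr-defined]
    logger.info(
        "clean_lane: %d barcodes in, %d prefiltered, %d removed as daughters, "
        "%d retained (%.2f s)",
        table.n_barcodes, len(prefiltered), len(removed), len(retained),
        time.perf_counter() - t0,
    )
    return result


def read_threshold_filter(table: ReadCountTable, threshold: int) -> list[str]:
    """Baseline filter: retain barcodes with lane-total reads >= threshold."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    totals = table.totals()
    return [b for b, t in totals.items() if t >= threshold]
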