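"""Performance metrics, the randomization control, and sample subsampling.

Metrics follow the usual confusion-matrix definitions over an explicit
universe of barcodes: sensitivity = tp/(tp+fn) (true barcodes recovered),
specificity = tn/(tn+fp) (spurious barcodes removed), precision = tp/(tp+fp)
(purity of what is left after filtering).  The randomization control
destroys the sequence-to-count-profile association the clean-up exploits, so
agreement with the truth after randomization measures chance overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .tables import ReadCountTable

__all__ = [
    "ConfusionCounts",
    "PerformanceMetrics",
    "evaluate",
    "randomize_table",
    "subsample_lane",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def universe_size(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceMetrics:
    """Sensitivity, specificity and precision; None when undefined."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None

    @classmethod
    def from_counts(cls, counts: ConfusionCounts) -> "PerformanceMetrics":
        def safe(num: int, den: int) -> float | None:
            return num / den if den > 0 else None

        return cls(
            sensitivity=safe(counts.tp, counts.tp + counts.fn),
            specificity=safe(counts.tn, counts.tn + counts.fp),
            precision=safe(counts.tp, counts.tp + counts.fp),
        )


def evaluate(
    predicted_true: Iterable[str],
    gold_true: Iterable[str],
    universe: Iterable[str],
) -> tuple[ConfusionCounts, PerformanceMetrics]:
    """Score a predicted set of true barcodes against a gold standard."""
    predicted = set(predicted_true)
    gold = set(gold_true)
    space = set(universe)
    if not predicted <= space:
        raise ValueError("predicted_true must be a subset of the universe")
    if not gold <= space:
        raise ValueError("gold_true must be a subset of the universe")
    tp = len(predicted & gold)
    fp = len(predicted - gold)
    fn = len(gold - predicted)
    tn = len(space) - tp - fp - fn
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    return counts, PerformanceMetrics.from_counts(counts)


def randomize_table(table: ReadCountTable, seed: int) -> ReadCountTable:
    """Destroy the structure the clean-up exploits, preserving marginals.

    First the barcode sequence labels are permuted uniformly at random
    across rows; then, independently for each row, the per-sample counts are
    permuted across samples.  Row totals and the multiset of sequences are
    unchanged, but sequence similarity no longer predicts count-profile
    similarity.
    """
    rng = np.random.default_rng(seed)
    barcodes = np.array(table.barcodes, dtype=object)
    shuffled = barcodes[rng.permutation(len(barcodes))]
    counts = table.matrix().copy()
    n_samples = counts.shape[1]
    for row in counts:
        row[:] = row[rng.permutation(n_samples)]
    frame = pd.DataFrame(counts, index=list(shuffled), columns=table.sample_ids)
    return ReadCountTable(frame, table.samples)


def subsample_lane(
    table: ReadCountTable, n_samples: int, seed: int
) -> ReadCountTable:
    """Keep a random subset of samples, rescaled to the original lane depth.

    A uniform random subset of ``n_samples`` columns is kept and every count
    is multiplied by (original grand total) / (kept grand total), rounded
    half-to-even.  This emulates sequencing the same lane with fewer
    multiplexed samples at the same depth.
    """
    if not (1 <= n_samples <= table.n_samples):
        raise ValueError(
            f"n_samples must lie in [1, {table.n_samples}], got {n_samples}"
        )
    rng = np.random.default_rng(seed)
    keep_idx = np.sort(rng.choice(table.n_samples, size=n_samples, replace=False))
    keep_ids = [table.sample_ids[i] for i in keep_idx]
    sub = table.subset_samples(keep_ids)
    kept_total = sub.grand_total()
    if kept_total == 0:
        return sub
    scale = table.grand_total() / kept_total
    counts = np.rint(sub.matrix() * scale).astype(np.int64)
    frame = pd.DataFrame(counts, index=sub.barcodes, columns=sub.sample_ids)
    return ReadCountTable(frame, sub.samples)
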