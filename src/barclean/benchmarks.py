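"""Standard synthetic-data experiments for validating the clean-up method.

Each function simulates a lane (or reuses one), runs a filtering method and
measures its performance against the simulator's ground truth.  Conventions:
the metric universe is the set of barcodes passing the prefilter in the
table being cleaned, the gold-standard true set is the mother clones, and
predicted-true is the retained set intersected with the universe.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .cleanup import clean_lane, prefilter, read_threshold_filter
from .evaluation import evaluate, randomize_table, subsample_lane
from .model import CleanupParams
from .simulate import SimulationConfig, SyntheticTruth, simulate_experiment
from .tables import ReadCountTable

__all__ = [
    "score_cleanup",
    "truth_recovery",
    "randomization_control",
    "subsample_precision",
    "threshold_sweep",
]


def _default_lane(seed: int, config: SimulationConfig | None):
    if config is None:
        config = SimulationConfig(seed=seed)
    tables, truth = simulate_experiment(config)
    lane = config.lane_ids()[0]
    return tables[lane], truth


def score_cleanup(
    table: ReadCountTable,
    truth: SyntheticTruth,
    params: CleanupParams = CleanupParams(),
    retained: set[str] | None = None,
):
    """Confusion counts and metrics for a retained set against the truth."""
    if retained is None:
        retained = set(clean_lane(table, params).retained)
    universe_table, _ = prefilter(table, params)
    universe = set(universe_table.barcodes)
    gold = truth.mother_sequences() & universe
    return evaluate(retained & universe, gold, universe)


def truth_recovery(
    seed: int, config: SimulationConfig | None = None,
    params: CleanupParams = CleanupParams(),
) -> dict:
    """Clean one simulated training-mix lane and score it against the truth.

    Reports how many mother clones survive the clean-up and what fraction of
    the reproducible error daughters is removed (a daughter counts as
    removed whether it was claimed by a mother, prefiltered, or never
    observed at all).
    """
    table, truth = _default_lane(seed, config)
    result = clean_lane(table, params)
    retained = set(result.retained)
    mothers = truth.mother_sequences()
    daughters = truth.daughter_sequences()
    counts, metrics = score_cleanup(table, truth, params, retained)
    return {
        "mothers_total": len(mothers),
        "mothers_retained": len(retained & mothers),
        "daughters_total": len(daughters),
        "daughters_removed": len(daughters - retained),
        "daughter_removal_fraction": len(daughters - retained) / len(daughters),
        "spurious_retained": len(retained - mothers),
        "confusion": counts,
        "metrics": metrics,
    }


def randomization_control(
    seed: int, randomize_seed: int | None = None,
    config: SimulationConfig | None = None,
    params: CleanupParams = CleanupParams(),
) -> dict:
    """Clean a lane before and after destroying its error structure.

    Randomization permutes barcode sequences across rows and counts across
    samples within rows; the truth-overlapping retained set after
    randomization measures how much of the clean-up's agreement with the
    truth could arise by chance.
    """
    if randomize_seed is None:
        randomize_seed = seed + 100
    table, truth = _default_lane(seed, config)
    mothers = truth.mother_sequences()
    plain = len(set(clean_lane(table, params).retained) & mothers)
    shuffled = randomize_table(table, randomize_seed)
    randomized = len(set(clean_lane(shuffled, params).retained) & mothers)
    return {
        "overlap_plain": plain,
        "overlap_randomized": randomized,
        "randomized_fraction": randomized / plain if plain else float("nan"),
    }


def subsample_precision(
    seed: int,
    sample_counts: Sequence[int] = (2, 4, 6, 8, 10, 12, 16, 20, 24),
    subsample_seeds: Sequence[int] = (1, 2, 3),
    config: SimulationConfig | None = None,
    params: CleanupParams = CleanupParams(),
) -> dict[int, float]:
    """Precision of the clean-up as a function of samples per lane.

    For each requested sample count, a random subset of columns (rescaled to
    the original lane depth) is cleaned; the mean precision over the
    subsample draws is returned.  Undefined precision counts as zero.
    """
    table, truth = _default_lane(seed, config)
    out: dict[int, float] = {}
    for n in sample_counts:
        precisions = []
        for sub_seed in subsample_seeds:
            sub = subsample_lane(table, n, sub_seed)
            _, metrics = score_cleanup(sub, truth, params)
            precisions.append(metrics.precision or 0.0)
        out[n] = float(np.mean(precisions))
    return out


def threshold_sweep(
    seed: int, config: SimulationConfig | None = None,
    params: CleanupParams = CleanupParams(),
) -> dict:
    """Best fixed read threshold versus the clean-up on one lane.

    Sweeps every distinct lane-total as a threshold and records the best
    simultaneously achievable min(sensitivity, precision); the clean-up's
    own sensitivity and precision are reported for comparison.
    """
    table, truth = _default_lane(seed, config)
    universe_table, _ = prefilter(table, params)
    universe = set(universe_table.barcodes)
    gold = truth.mother_sequences() & universe
    best = 0.0
    best_threshold = None
    for threshold in sorted(universe_table.totals().unique()):
        predicted = set(read_threshold_filter(universe_table, int(threshold)))
        _, metrics = evaluate(predicted, gold, universe)
        value = min(metrics.sensitivity or 0.0, metrics.precision or 0.0)
        if value > best:
            best, best_threshold = value, int(threshold)
    _, cleanup_metrics = score_cleanup(table, truth, params)
    return {
        "best_threshold": best_threshold,
        "best_threshold_min_sens_prec": best,
        "cleanup_sensitivity": cleanup_metrics.sensitivity,
        "cleanup_specificity": cleanup_metrics.specificity,
        "cleanup_precision": cleanup_metrics.precision,
    }
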