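"""Beta-binomial error model and the cross-sample log-likelihood score.

A spurious "daughter" barcode generated by a recurrent sequencing error is
expected to appear in every sample of a lane at a near-constant rate relative
to its "mother" barcode.  Writing ``m_i`` and ``c_i`` for the mother and
daughter read counts in sample ``i``, the total-frequency ratio
``r = sum(c_i)/sum(m_i)`` predicts ``r * m_i`` daughter reads per sample, and
the scatter of the observed ``c_i`` around that prediction is overdispersed
relative to a binomial.  The model therefore scores each sample with a
beta-binomial density ``f(c_i; m_i, alpha, beta)`` whose shape is fixed by the
mean/overdispersion parameterisation

    mu  = alpha / (alpha + beta)      (set to r)
    rho = 1 / (1 + alpha + beta)      (set to r / 10)

and summarises a candidate pair with the mean natural-log density over the
samples carrying enough reads (``m_i`` or ``c_i`` >= 200 by default).  The
resulting score ``l`` is compared against a read-depth-dependent threshold
line ``l = a * log10(sum(c_i)) + b``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "BetaBinomialShape",
    "PairScore",
    "CleanupParams",
    "LOG_DENSITY_FLOOR",
    "shape_from_mu_rho",
    "betabinom_log_density",
    "expected_daughter_reads",
    "loglik_score",
    "score_threshold",
]

#: Floor for per-sample log densities.  A sample with zero probability mass
#: (e.g. c_i > m_i) would otherwise send the mean score to -inf; flooring at
#: ln(1e-300) keeps arithmetic finite while still (correctly) destroying the
#: score of such a pair.
LOG_DENSITY_FLOOR = math.log(1e-300)


@dataclass(frozen=True)
class BetaBinomialShape:
    """Beta-binomial shape (alpha, beta), with the (mu, rho) read-out."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"alpha and beta must be positive, got "
                             f"({self.alpha}, {self.beta})")

    @property
    def mu(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def rho(self) -> float:
        return 1.0 / (1.0 + self.alpha + self.beta)


def shape_from_mu_rho(mu: float, rho: float) -> BetaBinomialShape:
    """Invert mu = a/(a+b), rho = 1/(1+a+b) to shape parameters."""
    if not (0.0 < mu < 1.0):
        raise ValueError(f"mu must lie in (0,1), got {mu}")
    if not (0.0 < rho < 1.0):
        raise ValueError(f"rho must lie in (0,1), got {rho}")
    s = 1.0 / rho - 1.0  # alpha + beta
    return BetaBinomialShape(alpha=mu * s, beta=(1.0 - mu) * s)


def betabinom_log_density(c, n, shape: BetaBinomialShape):
    """Natural log of the beta-binomial pmf of ``c`` successes in ``n`` trials.

    Evaluated via log-gamma for numerical stability:

        ln f = ln C(n, c) + ln B(c + alpha, n - c + beta) - ln B(alpha, beta)

    Accepts scalars or arrays (broadcast together).  Impossible outcomes
    (c > n) and astronomically small masses are floored at
    :data:`LOG_DENSITY_FLOOR`.
    """
    a, b = shape.alpha, shape.beta
    c_arr = np.asarray(c, dtype=np.float64)
    n_arr = np.asarray(n, dtype=np.float64)
    c_arr, n_arr = np.broadcast_arrays(c_arr, n_arr)
    if (c_arr < 0).any() or (n_arr < 0).any():
        raise ValueError("counts must be non-negative")
    impossible = c_arr > n_arr
    cc = np.where(impossible, n_arr, c_arr)  # keep gammaln arguments valid
    out = (
        gammaln(n_arr + 1.0) - gammaln(cc + 1.0) - gammaln(n_arr - cc + 1.0)
        + gammaln(cc + a) + gammaln(n_arr - cc + b) - gammaln(n_arr + a + b)
        - (gammaln(a) + gammaln(b) - gammaln(a + b))
    )
    out = np.where(impossible, LOG_DENSITY_FLOOR, out)
    out = np.maximum(out, LOG_DENSITY_FLOOR)
    if out.ndim == 0:
        return float(out)
    return out


def expected_daughter_reads(ratio: float, mother_reads) -> float:
    """Predicted daughter reads in a sample: ratio times the mother's reads."""
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    return ratio * mother_reads


@dataclass(frozen=True)
class CleanupParams:
    """All cutoffs of the clean-up method, defaulted to the published values.

    max_dist
        Maximal Levenshtein distance d_L for a mother-daughter pair.
    max_ratio
        Maximal total-frequency ratio r (the estimated per-error rate).
    slope_a, offset_b
        Slope and offset of the score threshold line
        ``l = a * log10(total daughter reads) + b``.
    min_total_reads
        Prefilter: barcodes with fewer lane-total reads are excluded.
    min_sample_reads
        A sample contributes to the score only when the mother or the
        daughter carries at least this many reads in it.
    rho_divisor
        Overdispersion is fixed to ``rho = r / rho_divisor``.
    """

    max_dist: int = 4
    max_ratio: float = 0.05
    slope_a: float = -2.0
    offset_b: float = -1.0
    min_total_reads: int = 100
    min_sample_reads: int = 200
    rho_divisor: float = 10.0

    def __post_init__(self):
        if self.max_dist < 1:
            raise ValueError("max_dist must be >= 1")
        if not (0.0 < self.max_ratio < 1.0):
            raise ValueError("max_ratio must lie in (0,1)")
        if self.min_total_reads < 1 or self.min_sample_reads < 1:
            raise ValueError("read cutoffs must be >= 1")
        if self.rho_divisor <= 1.0:
            raise ValueError("rho_divisor must exceed 1 (ensures rho < mu)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, values: dict) -> "CleanupParams":
        return cls(**values)


@dataclass(frozen=True)
class PairScore:
    """Everything the model computes for one candidate mother-daughter pair."""

    ratio: float
    loglik: float | None
    n_qualifying: int
    threshold: float | None
    total_daughter: int
    total_mother: int


def score_threshold(total_daughter_reads: int, params: CleanupParams) -> float:
    """Threshold line ``a * log10(total daughter reads) + b``."""
    if total_daughter_reads < 1:
        raise ValueError("total daughter reads must be >= 1")
    return params.slope_a * math.log10(total_daughter_reads) + params.offset_b


def loglik_score(
    daughter_counts: Sequence[int],
    mother_counts: Sequence[int],
    params: CleanupParams = CleanupParams(),
) -> PairScore:
    """Score the cross-sample predictability of a candidate daughter.

    The two count vectors must be aligned to the same sample order.  The
    score is the mean natural-log beta-binomial density (mu = r,
    rho = r / rho_divisor, trials = mother reads) over the qualifying
    samples; it is undefined (``loglik is None``) when no sample qualifies or
    when the ratio is degenerate (r = 0 or r >= 1).
    """
    c = np.asarray(daughter_counts, dtype=np.int64)
    m = np.asarray(mother_counts, dtype=np.int64)
    if c.ndim != 1 or c.shape != m.shape or c.size == 0:
        raise ValueError("count vectors must be equal-length 1-D and non-empty")
    if (c < 0).any() or (m < 0).any():
        raise ValueError("counts must be non-negative")
    total_m = int(m.sum())
    total_c = int(c.sum())
    if total_m == 0:
        raise ValueError("mother has zero total reads")
    ratio = total_c / total_m
    qualifying = (m >= params.min_sample_reads) | (c >= params.min_sample_reads)
    n_qualifying = int(qualifying.sum())
    threshold = score_threshold(total_c, params) if total_c >= 1 else None
    loglik = None
    if n_qualifying >= 1 and 0.0 < ratio < 1.0:
        shape = shape_from_mu_rho(ratio, ratio / params.rho_divisor)
        dens = betabinom_log_density(c[qualifying], m[qualifying], shape)
        loglik = float(np.mean(dens))
    return PairScore(
        ratio=ratio,
        loglik=loglik,
        n_qualifying=n_qualifying,
        threshold=threshold,
        total_daughter=total_c,
        total_mother=total_m,
    )
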