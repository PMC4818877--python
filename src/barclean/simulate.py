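"""Synthetic barcode count data with known ground truth.

The generator emulates the clone-mix design used to calibrate the clean-up
method: ~20 mother clones whose abundances follow a two-fold geometric
series, sequenced as technical replicate pairs in one or more multiplexed
lanes.  Each mother spawns a handful of reproducible error daughters whose
per-error rate is constant across samples within a lane (beta-binomially
overdispersed around rate * mother reads) but can differ up to ten-fold
between lanes, plus a large tail of rare, unreproducible noise variants, a
few replicate-specific early-PCR artifacts, and rare contaminants.

Everything is generated at read-count resolution: mother reads per sample
are multinomial over the clone fractions (with per-replicate-group
lognormal abundance jitter shared by the two technical replicates of a
group), so the smallest clone stays detectable at default depth.  A small
FASTQ scaffold writer is included so the demultiplexing stage can be tested
end to end.

Also houses the elementary error-combinatorics helpers (single-substitution
variant enumeration, expected fraction of error-free reads).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from typing import TextIO

import numpy as np
import pandas as pd

from .demux import ExtractionSpec
from .distance import levenshtein
from .tables import ReadCountTable, SampleMeta

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "MotherClone",
    "ErrorDaughter",
    "PcrArtifact",
    "Contaminant",
    "NoiseVariant",
    "enumerate_snv_variants",
    "correct_read_fraction",
    "simulate_experiment",
    "write_fastq",
]

BASES = "ACGT"


# ---------------------------------------------------------------------------
# error-count arithmetic


def enumerate_snv_variants(seq: str) -> list[str]:
    """All single-substitution variants of ``seq`` (3 * len(seq) of them)."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    if set(seq) - set(BASES):
        raise ValueError(f"sequence must contain only ACGT: {seq!r}")
    variants = []
    for pos, base in enumerate(seq):
        for other in BASES:
            if other != base:
                variants.append(seq[:pos] + other + seq[pos + 1:])
    return variants


def correct_read_fraction(per_base_error: float, length: int) -> float:
    """Expected fraction of error-free reads over ``length`` nucleotides."""
    if not (0.0 <= per_base_error < 1.0):
        raise ValueError("per_base_error must lie in [0,1)")
    if length < 0:
        raise ValueError("length must be non-negative")
    return (1.0 - per_base_error) ** length


# ---------------------------------------------------------------------------
# configuration and ground truth


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of the synthetic experiment.

    Defaults reproduce the calibration design: 20 clones in a two-fold
    geometric series (spanning ~5e5-fold), 12 replicate groups = 24 samples
    per lane, ~10 reproducible error daughters per mother with per-error
    rates log-uniform between 1e-5 and 10^-1.3 (~0.05; higher rates occur
    only exceptionally in real data), overdispersion rho = rate/10.
    """

    n_mothers: int = 20
    abundance_ratio: float = 2.0
    smallest_clone: float = 10.0
    n_replicate_groups: int = 12
    n_lanes: int = 1
    barcode_length: int = 15
    errors_per_mother: int = 10
    error_rate_log10_range: tuple[float, float] = (-5.0, -1.3)
    between_lane_rate_factor: float = 10.0
    overdispersion_divisor: float = 10.0
    pcr_error_rate: float = 0.002
    contaminant_count: int = 5
    noise_variants_per_mother: int = 180
    noise_reads_range: tuple[int, int] = (1, 30)
    group_abundance_sigma: float = 0.3
    daughter_distance_probs: tuple[float, ...] = (0.70, 0.15, 0.10, 0.05)
    min_mother_distance: int = 5
    reads_per_sample: int = 25_000_000
    seed: int = 0

    def __post_init__(self):
        if self.n_mothers < 1 or self.n_replicate_groups < 1 or self.n_lanes < 1:
            raise ValueError("counts must be positive")
        if self.abundance_ratio <= 1.0:
            raise ValueError("abundance_ratio must exceed 1")
        if self.barcode_length < 1:
            raise ValueError("barcode_length must be >= 1")
        lo, hi = self.error_rate_log10_range
        if not (lo < hi and 10.0 ** hi < 1.0):
            raise ValueError("error_rate_log10_range must be increasing, rates < 1")
        if self.overdispersion_divisor <= 1.0:
            raise ValueError("overdispersion_divisor must exceed 1")
        if not (0.0 <= self.pcr_error_rate < 1.0):
            raise ValueError("pcr_error_rate must lie in [0,1)")
        if abs(sum(self.daughter_distance_probs) - 1.0) > 1e-9:
            raise ValueError("daughter_distance_probs must sum to 1")
        needed = self.n_mothers * (
            1 + self.errors_per_mother + self.noise_variants_per_mother
        ) + self.contaminant_count
        if needed > 4 ** self.barcode_length / 4:
            raise ValueError(
                f"{needed} unique sequences demanded of a length-"
                f"{self.barcode_length} barcode space"
            )

    def lane_ids(self) -> list[str]:
        return [f"lane{i + 1}" for i in range(self.n_lanes)]


@dataclass(frozen=True)
class MotherClone:
    sequence: str
    clone_size: float
    expected_fraction: float


@dataclass(frozen=True)
class ErrorDaughter:
    sequence: str
    mother: str
    distance: int
    rate_by_lane: dict  # lane_id -> per-error rate e


@dataclass(frozen=True)
class PcrArtifact:
    sequence: str
    mother: str
    sample_id: str
    lane_id: str


@dataclass(frozen=True)
class Contaminant:
    sequence: str
    sample_id: str
    lane_id: str


@dataclass(frozen=True)
class NoiseVariant:
    sequence: str
    mother: str
    lane_id: str


@dataclass
class SyntheticTruth:
    """Ground-truth labels emitted alongside the simulated tables."""

    mothers: list[MotherClone] = field(default_factory=list)
    error_daughters: list[ErrorDaughter] = field(default_factory=list)
    pcr_artifacts: list[PcrArtifact] = field(default_factory=list)
    contaminants: list[Contaminant] = field(default_factory=list)
    noise_variants: list[NoiseVariant] = field(default_factory=list)

    def mother_sequences(self) -> set[str]:
        return {m.sequence for m in self.mothers}

    def daughter_sequences(self) -> set[str]:
        return {d.sequence for d in self.error_daughters}

    def spurious_sequences(self) -> set[str]:
        return (
            self.daughter_sequences()
            | {p.sequence for p in self.pcr_artifacts}
            | {c.sequence for c in self.contaminants}
            | {v.sequence for v in self.noise_variants}
        )


# ---------------------------------------------------------------------------
# sequence drawing helpers


def _random_barcode(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _draw_mothers(rng: np.random.Generator, cfg: SimulationConfig) -> list[str]:
    """Random barcodes kept pairwise at least min_mother_distance apart.

    Keeping mothers well separated makes the ground-truth mother of every
    simulated daughter unambiguous (daughters sit within max_dist of exactly
    one mother).
    """
    mothers: list[str] = []
    for _ in range(20_000):
        cand = _random_barcode(rng, cfg.barcode_length)
        if all(levenshtein(cand, m) >= cfg.min_mother_distance for m in mothers):
            mothers.append(cand)
            if len(mothers) == cfg.n_mothers:
                return mothers
    raise RuntimeError("could not place mothers at the requested distance")


def _substituted_variant(
    rng: np.random.Generator, seq: str, distance: int, taken: set[str]
) -> str:
    """A fresh variant at exact Levenshtein distance ``distance`` from seq."""
    for d in range(distance, distance + 3):  # escalate if the space is exhausted
        for _ in range(500):
            positions = rng.choice(len(seq), size=d, replace=False)
            chars = list(seq)
            for pos in positions:
                chars[pos] = rng.choice([b for b in BASES if b != seq[pos]])
            cand = "".join(chars)
            if cand not in taken and levenshtein(cand, seq) == d:
                return cand
    raise RuntimeError("could not draw a fresh variant")


# ---------------------------------------------------------------------------
# the experiment


def simulate_experiment(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[dict[str, ReadCountTable], SyntheticTruth]:
    """Generate per-lane count tables plus the ground truth.

    Fully reproducible from ``config.seed``.  Barcodes that end up with zero
    reads in a lane are absent from that lane's table (as they would be in
    real data) but remain in the truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    truth = SyntheticTruth()
    taken: set[str] = set()

    # mothers and the geometric clone-size series
    mother_seqs = _draw_mothers(rng, cfg)
    taken.update(mother_seqs)
    sizes = cfg.smallest_clone * cfg.abundance_ratio ** np.arange(cfg.n_mothers)
    fractions = sizes / sizes.sum()
    for seq, size, frac in zip(mother_seqs, sizes, fractions):
        truth.mothers.append(MotherClone(seq, float(size), float(frac)))

    # reproducible error daughters: base rate, per-lane downward jitter
    lo, hi = cfg.error_rate_log10_range
    distances = rng.choice(
        np.arange(1, len(cfg.daughter_distance_probs) + 1),
        size=(cfg.n_mothers, cfg.errors_per_mother),
        p=cfg.daughter_distance_probs,
    )
    daughters: list[ErrorDaughter] = []
    for k, mother in enumerate(mother_seqs):
        for j in range(cfg.errors_per_mother):
            seq = _substituted_variant(rng, mother, int(distances[k, j]), taken)
            taken.add(seq)
            base = 10.0 ** rng.uniform(lo, hi)
            if cfg.n_lanes > 1:
                factors = cfg.between_lane_rate_factor ** rng.uniform(
                    0.0, 1.0, size=cfg.n_lanes
                )
            else:
                factors = np.ones(1)
            rate_by_lane = {
                lane: float(base / f)
                for lane, f in zip(cfg.lane_ids(), factors)
            }
            daughters.append(ErrorDaughter(seq, mother, int(distances[k, j]),
                                           rate_by_lane))
    truth.error_daughters = daughters

    tables: dict[str, ReadCountTable] = {}
    for lane in cfg.lane_ids():
        tables[lane] = _simulate_lane(rng, cfg, lane, mother_seqs, fractions,
                                      daughters, truth, taken)
    return tables, truth


def _simulate_lane(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    lane: str,
    mother_seqs: list[str],
    fractions: np.ndarray,
    daughters: list[ErrorDaughter],
    truth: SyntheticTruth,
    taken: set[str],
) -> ReadCountTable:
    n_groups = cfg.n_replicate_groups
    n_samples = 2 * n_groups
    samples = []
    for g in range(n_groups):
        for half in "ab":
            samples.append(SampleMeta(
                sample_id=f"{lane}_g{g:02d}{half}",
                lane_id=lane,
                replicate_group=f"{lane}_g{g:02d}",
            ))

    # mother reads: multinomial over jittered clone fractions; both technical
    # replicates of a group share the group's jittered composition
    mother_counts = np.zeros((len(mother_seqs), n_samples), dtype=np.int64)
    for g in range(n_groups):
        jitter = 10.0 ** rng.normal(0.0, cfg.group_abundance_sigma,
                                    size=len(mother_seqs))
        p = fractions * jitter
        p = p / p.sum()
        for rep in range(2):
            mother_counts[:, 2 * g + rep] = rng.multinomial(
                cfg.reads_per_sample, p)

    rows: dict[str, np.ndarray] = {
        seq: mother_counts[k] for k, seq in enumerate(mother_seqs)
    }
    mother_index = {seq: k for k, seq in enumerate(mother_seqs)}

    # reproducible error daughters: beta-binomial around rate * mother reads
    for daughter in daughters:
        e = daughter.rate_by_lane[lane]
        s = cfg.overdispersion_divisor / e - 1.0  # alpha + beta for rho=e/div
        alpha, beta = e * s, (1.0 - e) * s
        m = rows[daughter.mother]
        p = rng.beta(alpha, beta, size=n_samples)
        rows[daughter.sequence] = rng.binomial(m, p)

    # rare unreproducible noise variants (the long tail of distinct errors)
    lo_n, hi_n = cfg.noise_reads_range
    for mother in mother_seqs:
        profile = rows[mother] / rows[mother].sum()
        for _ in range(cfg.noise_variants_per_mother):
            seq = _substituted_variant(
                rng, mother, int(rng.choice([1, 2, 3], p=[0.15, 0.45, 0.40])),
                taken)
            taken.add(seq)
            total = int(math.floor(math.exp(
                rng.uniform(math.log(lo_n), math.log(hi_n + 1)))))
            rows[seq] = rng.multinomial(max(total, 1), profile)
            truth.noise_variants.append(NoiseVariant(seq, mother, lane))

    # early-PCR artifacts: present in a single technical replicate only
    for mother in mother_seqs:
        hit = rng.random(n_samples) < cfg.pcr_error_rate
        for i in np.flatnonzero(hit):
            rate = 10.0 ** rng.uniform(-5.0, -2.0)
            reads = rng.binomial(rows[mother][i], rate)
            if reads == 0:
                continue
            seq = _substituted_variant(rng, mother, 1, taken)
            taken.add(seq)
            counts = np.zeros(n_samples, dtype=np.int64)
            counts[i] = reads
            rows[seq] = counts
            truth.pcr_artifacts.append(
                PcrArtifact(seq, mother, samples[i].sample_id, lane))

    # rare physical contaminants, also single-replicate
    for _ in range(cfg.contaminant_count):
        for _ in range(1000):
            seq = _random_barcode(rng, cfg.barcode_length)
            if seq not in taken and all(
                levenshtein(seq, m) >= cfg.min_mother_distance
                for m in mother_seqs
            ):
                break
        taken.add(seq)
        i = int(rng.integers(n_samples))
        counts = np.zeros(n_samples, dtype=np.int64)
        counts[i] = int(rng.integers(10, 80))
        rows[seq] = counts
        truth.contaminants.append(Contaminant(seq, samples[i].sample_id, lane))

    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=[s.sample_id for s in samples])
    frame = frame.astype(np.int64)
    frame = frame[frame.sum(axis=1) > 0]  # unobserved sequences do not appear
    return ReadCountTable(frame, samples)


# ---------------------------------------------------------------------------
# FASTQ scaffold (for end-to-end demultiplexing tests)

DEFAULT_PRIMER = "GATCTGACGTCGCA"


def write_fastq(
    table: ReadCountTable,
    path,
    primer: str = DEFAULT_PRIMER,
    index_length: int = 6,
    prefix: str = "TTACG",
    suffix: str = "CA",
    seed: int = 0,
) -> ExtractionSpec:
    """Wrap every counted barcode into reads ``prefix+primer+index+barcode+suffix``.

    One read is emitted per counted read, in a deterministic shuffled order,
    with a distinct sample index per column; no additional errors are
    injected.  Returns the :class:`~barclean.demux.ExtractionSpec` that
    recovers ``table`` exactly.  Intended for small tables only.
    """
    rng = np.random.default_rng(seed)
    indices: list[str] = []
    while len(indices) < table.n_samples:
        cand = _random_barcode(rng, index_length)
        if cand not in indices:
            indices.append(cand)
    index_to_sample = dict(zip(indices, table.sample_ids))
    spec = ExtractionSpec(
        primer_constant=primer,
        index_offset=0,
        index_length=index_length,
        barcode_offset=index_length,
        barcode_length=len(table.barcodes[0]) if table.barcodes else 15,
        index_to_sample=index_to_sample,
    )
    reads = []
    matrix = table.matrix()
    for bi, barcode in enumerate(table.barcodes):
        for si, index in enumerate(indices):
            count = int(matrix[bi, si])
            if count:
                reads.extend([(barcode, index)] * count)
    order = rng.permutation(len(reads))

    handle: TextIO
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as handle:
        for n, ridx in enumerate(order):
            barcode, index = reads[ridx]
            seq = prefix + primer + index + barcode + suffix
            handle.write(f"@read{n}\n{seq}\n+\n{'I' * len(seq)}\n")
    return spec
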