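"""FASTQ demultiplexing: primer anchoring, index matching, barcode extraction.

Reads are anchored on the first exact occurrence of a constant primer
fragment; the sample index and the barcode are then cut out at fixed offsets
relative to the position immediately after the primer match (0-based).  The
index must match one of the configured sample indices exactly — no fuzzy
matching and no index-hopping correction.  Quality scores are ignored.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .tables import BARCODE_ALPHABET, ReadCountTable, SampleMeta

__all__ = ["ExtractionSpec", "DiscardTally", "extract_barcodes", "extract_fastq"]


class MalformedFastqError(ValueError):
    """Raised when the FASTQ stream cannot be parsed, naming the record."""


@dataclass(frozen=True)
class ExtractionSpec:
    """Where to find the index and barcode relative to the primer match.

    ``index_offset`` and ``barcode_offset`` are 0-based positions counted
    from the character immediately after the primer match (negative offsets
    reach back into or before the primer).
    """

    primer_constant: str
    index_offset: int
    index_length: int
    barcode_offset: int
    barcode_length: int = 15
    index_to_sample: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.primer_constant or set(self.primer_constant) - set("ACGT"):
            raise ValueError("primer_constant must be non-empty A/C/G/T")
        if self.barcode_length < 1 or self.index_length < 1:
            raise ValueError("index_length and barcode_length must be >= 1")
        if not self.index_to_sample:
            raise ValueError("index_to_sample must not be empty")
        if any(len(i) != self.index_length for i in self.index_to_sample):
            raise ValueError("all index sequences must have index_length")
        samples = list(self.index_to_sample.values())
        if len(set(samples)) != len(samples):
            raise ValueError("sample ids must be unique across indices")


@dataclass
class DiscardTally:
    """Why reads were not assigned to any (barcode, sample) cell."""

    no_primer: int = 0
    unknown_index: int = 0
    truncated: int = 0
    invalid_barcode: int = 0

    @property
    def total(self) -> int:
        return (self.no_primer + self.unknown_index + self.truncated
                + self.invalid_barcode)


def _iter_sequences(reads: Iterable) -> Iterator[str]:
    for read in reads:
        if isinstance(read, str):
            yield read.upper()
        elif isinstance(read, tuple):  # (title, sequence[, quality])
            yield str(read[1]).upper()
        else:  # Bio.SeqRecord
            yield str(read.seq).upper()


def extract_barcodes(
    reads: Iterable,
    spec: ExtractionSpec,
    samples: Sequence[SampleMeta] | None = None,
) -> tuple[ReadCountTable, DiscardTally]:
    """Build a barcode-by-sample count table from raw reads.

    ``reads`` may be strings, (title, sequence) tuples or SeqRecords.  Every
    sample in ``spec.index_to_sample`` gets a column, even if no read maps
    to it.  If ``samples`` metadata is given it must cover exactly the
    sample ids of the spec; otherwise minimal metadata is synthesised.
    """
    counters: dict[str, Counter] = {
        sid: Counter() for sid in spec.index_to_sample.values()
    }
    tally = DiscardTally()
    primer = spec.primer_constant
    for seq in _iter_sequences(reads):
        pos = seq.find(primer)
        if pos < 0:
            tally.no_primer += 1
            continue
        anchor = pos + len(primer)
        i0 = anchor + spec.index_offset
        b0 = anchor + spec.barcode_offset
        if min(i0, b0) < 0 or max(i0 + spec.index_length,
                                  b0 + spec.barcode_length) > len(seq):
            tally.truncated += 1
            continue
        index = seq[i0:i0 + spec.index_length]
        sample_id = spec.index_to_sample.get(index)
        if sample_id is None:
            tally.unknown_index += 1
            continue
        barcode = seq[b0:b0 + spec.barcode_length]
        if set(barcode) - BARCODE_ALPHABET:
            tally.invalid_barcode += 1
            continue
        counters[sample_id][barcode] += 1

    if samples is None:
        samples = [SampleMeta(sample_id=sid)
                   for sid in spec.index_to_sample.values()]
    else:
        samples = list(samples)
        if [s.sample_id for s in samples] != list(spec.index_to_sample.values()):
            raise ValueError("sample metadata does not match the spec's samples")

    barcodes = sorted({b for counter in counters.values() for b in counter})
    matrix = np.zeros((len(barcodes), len(samples)), dtype=np.int64)
    for si, meta in enumerate(samples):
        counter = counters[meta.sample_id]
        for bi, barcode in enumerate(barcodes):
            if barcode in counter:
                matrix[bi, si] = counter[barcode]
    frame = pd.DataFrame(matrix, index=barcodes,
                         columns=[s.sample_id for s in samples])
    return ReadCountTable(frame, samples), tally


def extract_fastq(
    path,
    spec: ExtractionSpec,
    samples: Sequence[SampleMeta] | None = None,
) -> tuple[ReadCountTable, DiscardTally]:
    """Run :func:`extract_barcodes` on a FASTQ file (plain or gzip)."""
    opener = gzip.open if str(path).endswith(".gz") else open

    def _records():
        with opener(path, "rt") as handle:
            record_no = 0
            try:
                for title, seq, qual in FastqGeneralIterator(handle):
                    record_no += 1
                    yield seq
            except ValueError as err:
                raise MalformedFastqError(
                    f"malformed FASTQ near record {record_no + 1} in {path}: {err}"
                ) from err

    return extract_barcodes(_records(), spec, samples)
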