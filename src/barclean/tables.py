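"""Read-count tables and sample metadata.

The whole clean-up method operates on a single quantitative object: a table of
integer read counts with one row per (unfiltered) barcode sequence and one
column per multiplexed sample.  Columns carry metadata describing which
sequencing lane they belong to and which technical-replicate pair they form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: characters permitted in a barcode as it comes off the sequencer
BARCODE_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one count-table column (one technical replicate).

    Parameters
    ----------
    sample_id
        Unique identifier of the column.
    lane_id
        The multiplexed sequencing lane this sample was run in.  The method's
        central assumption (per-error rates constant across samples) holds
        within a lane only, so all clean-up operations are per-lane.
    replicate_group
        The biological sample of which this column is one of (at most) two
        technical replicates.  Defaults to ``sample_id`` (no pairing known).
    index_sequence
        The sample index used during demultiplexing, if known.
    """

    sample_id: str
    lane_id: str = "lane1"
    replicate_group: str | None = None
    index_sequence: str | None = None

    def __post_init__(self):
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.replicate_group is None:
            object.__setattr__(self, "replicate_group", self.sample_id)


class ReadCountTable:
    """Barcode-by-sample matrix of non-negative integer read counts.

    Wraps a :class:`pandas.DataFrame` (index: barcode sequences, columns:
    sample ids) together with per-column :class:`SampleMeta`.
    """

    def __init__(self, counts: pd.DataFrame, samples: Sequence[SampleMeta]):
        samples = list(samples)
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in metadata")
        if list(counts.columns) != ids:
            raise ValueError(
                "count-table columns do not match sample metadata: "
                f"{list(counts.columns)} vs {ids}"
            )
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate barcode rows: {dups[:5]}")
        lengths = {len(b) for b in counts.index}
        if len(lengths) > 1:
            raise ValueError(f"barcodes of unequal length: {sorted(lengths)}")
        bad = [b for b in counts.index if set(b) - BARCODE_ALPHABET]
        if bad:
            raise ValueError(f"barcode with characters outside ACGTN: {bad[:5]}")
        values = counts.to_numpy()
        if values.size and (
            not np.issubdtype(values.dtype, np.integer) or (values < 0).any()
        ):
            raise ValueError("counts must be non-negative integers")
        self.counts = counts.astype(np.int64, copy=False)
        self.samples = samples

    # -- convenience accessors -------------------------------------------------

    @property
    def barcodes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def lane_ids(self) -> list[str]:
        return sorted({s.lane_id for s in self.samples})

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def matrix(self) -> np.ndarray:
        """Counts as an (n_barcodes, n_samples) int64 array."""
        return self.counts.to_numpy()

    def totals(self) -> pd.Series:
        """Lane-total reads per barcode (sum over all samples)."""
        return self.counts.sum(axis=1)

    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    # -- subsetting ------------------------------------------------------------

    def subset_barcodes(self, keep: Iterable[str]) -> "ReadCountTable":
        keep = [b for b in self.barcodes if b in set(keep)]
        return ReadCountTable(self.counts.loc[keep], self.samples)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ReadCountTable":
        meta = {s.sample_id: s for s in self.samples}
        return ReadCountTable(
            self.counts[list(sample_ids)], [meta[i] for i in sample_ids]
        )

    @classmethod
    def from_arrays(
        cls,
        barcodes: Sequence[str],
        samples: Sequence[SampleMeta],
        counts: np.ndarray,
    ) -> "ReadCountTable":
        frame = pd.DataFrame(
            np.asarray(counts, dtype=np.int64),
            index=list(barcodes),
            columns=[s.sample_id for s in samples],
        )
        return cls(frame, samples)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ReadCountTable({self.n_barcodes} barcodes x {self.n_samples} "
            f"samples, lanes={self.lane_ids})"
        )
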