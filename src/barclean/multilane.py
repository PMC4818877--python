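"""Combining cleaned lanes: in silico reference libraries and rescue.

A barcode that is true but removed as a presumed daughter in one lane may
survive cleaning in another lane of the same experiment.  Joining the
retained barcodes of all lanes yields an in silico reference library, which
can then be used to rescue such barcodes lane by lane — the computational
analogue of filtering against an independently sequenced reference library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .cleanup import CleanupResult, prefilter
from .model import CleanupParams
from .tables import ReadCountTable

__all__ = [
    "BarcodeLibrary",
    "build_insilico_library",
    "rescue_with_library",
    "filter_by_reference",
]


@dataclass
class BarcodeLibrary:
    """A set of barcode sequences with the lanes each one survived in."""

    sequences: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __contains__(self, sequence: str) -> bool:
        return sequence in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def add(self, sequence: str, lane_id: str) -> None:
        self.sequences.add(sequence)
        self.provenance.setdefault(sequence, set()).add(lane_id)


def build_insilico_library(
    results: Sequence[tuple[str, CleanupResult]],
) -> BarcodeLibrary:
    """Union of retained barcodes across cleaned lanes, with provenance."""
    if not results:
        raise ValueError("at least one cleaned lane is required")
    library = BarcodeLibrary()
    for lane_id, result in results:
        for sequence in result.retained:
            library.add(sequence, lane_id)
    return library


def rescue_with_library(
    table: ReadCountTable,
    result: CleanupResult,
    library: BarcodeLibrary | Iterable[str],
    params: CleanupParams | None = None,
) -> CleanupResult:
    """Move library members back into the retained set of one lane.

    Any barcode of ``table`` that passes the prefilter (read cutoff, no N)
    and whose sequence is in the library is retained, even if the clean-up
    had removed it as a daughter.  Counts are never altered; the prefilter
    still applies so the universe of considered barcodes stays consistent
    across filtering methods.
    """
    if params is None:
        params = result.params
    member = set(library.sequences if isinstance(library, BarcodeLibrary) else library)
    eligible, _ = prefilter(table, params)
    rescuable = set(eligible.barcodes) & member

    already = set(result.retained)
    rescued = sorted(rescuable - already)
    retained = list(result.retained) + rescued
    removed = [ev for ev in result.removed_as_daughter
               if ev.daughter not in rescuable]
    return CleanupResult(
        retained=retained,
        removed_as_daughter=removed,
        removed_by_prefilter=list(result.removed_by_prefilter),
        params=params,
        rescued=rescued,
    )


def filter_by_reference(
    table: ReadCountTable, reference: BarcodeLibrary | Iterable[str]
) -> list[str]:
    """Gold-standard filter: retain exactly the barcodes in the reference."""
    member = set(reference.sequences if isinstance(reference, BarcodeLibrary) else reference)
    return [b for b in table.barcodes if b in member]
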