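"""Levenshtein edit distance between barcode sequences.

The clean-up method uses the plain Levenshtein distance d_L (unit-cost
substitutions, insertions and deletions; no transpositions) to decide whether
two barcodes are close enough to be an error pair.  Computation is delegated
to edlib's global (Needleman-Wunsch) alignment in distance-only mode.
"""

from __future__ import annotations

import edlib

__all__ = ["levenshtein"]


def levenshtein(a: str, b: str) -> int:
    """Exact Levenshtein distance between two non-empty sequences."""
    if not a or not b:
        raise ValueError("levenshtein requires non-empty sequences")
    return int(edlib.align(a, b, mode="NW", task="distance")["editDistance"])
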