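"""Semi-global minimum edit distance between a short pattern and a text.

The distance is the minimum over all substrings t of the text of the edit
distance between the pattern and t: the pattern must be fully consumed while
the text's flanks are free.  Patterns up to 64 symbols run through Myers'
bit-parallel algorithm (one machine word); longer patterns fall back to the
classic banded-free O(mn) dynamic program.  Both paths return identical
distances; the tests cross-check them against each other and against an
independent DP oracle.
"""

from __future__ import annotations

import numpy as np

from . import dna
from ._kernels import dp_min_distance, myers_min_distance


def _as_codes(s: str | np.ndarray) -> np.ndarray:
    if isinstance(s, str):
        return dna.encode(s)
    return np.asarray(s, dtype=np.uint8)


def min_edit_distance(pattern: str | np.ndarray, text: str | np.ndarray) -> int:
    """Minimum semi-global edit distance of pattern against text."""
    d, _ = min_edit_distance_end(pattern, text)
    return d


def min_edit_distance_end(
    pattern: str | np.ndarray, text: str | np.ndarray
) -> tuple[int, int]:
    """Distance plus the text end position of the best-matching substring."""
    pat = _as_codes(pattern)
    txt = _as_codes(text)
    if pat.size == 0 or txt.size == 0:
        raise ValueError("pattern and text must be non-empty")
    if pat.size <= 64:
        d, end = myers_min_distance(pat, txt)
    else:
        d, end = dp_min_distance(pat, txt)
    return int(d), int(end)
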