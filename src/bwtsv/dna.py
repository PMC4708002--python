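"""Byte-level DNA alphabet utilities shared across the package.

Sequences are handled internally as ``numpy.uint8`` arrays over the ranked
alphabet ``$ < A < C < G < T`` (codes 0..4).  The sentinel ``$`` terminates
indexed strings and separates chromosomes in the global genome coordinate
system; it never occurs inside a pattern.
"""

from __future__ import annotations

import numpy as np

SENTINEL = 0
A, C, G, T = 1, 2, 3, 4
ALPHABET = "$ACGT"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate(ALPHABET):
    _ENCODE[ord(_ch)] = _i
    _ENCODE[ord(_ch.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

# complement in code space: A<->T, C<->G, '$' fixed
_COMPLEMENT = np.array([0, 4, 3, 2, 1], dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode an ACGT string to the internal uint8 code array.

    Raises ``ValueError`` on characters outside ``$ACGTacgt`` (including N).
    """
    if isinstance(seq, str):
        seq = seq.encode()
    arr = _ENCODE[np.frombuffer(seq, dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        bad = chr(np.frombuffer(seq, dtype=np.uint8)[arr == 255][0])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode()


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement in code space."""
    return _COMPLEMENT[arr[::-1]]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def is_valid_read(seq: str) -> bool:
    """True iff the read is non-empty and strictly over ACGT (no N, no $)."""
    if not seq:
        return False
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    return bool(arr.size) and int(arr.min()) >= 1 and int(arr.max()) <= 4
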