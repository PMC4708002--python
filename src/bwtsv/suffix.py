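"""Suffix-array and LCP construction over byte texts.

The construction is a packed prefix-doubling scheme: the first sort key packs
16 three-bit symbols into one int64, after which ordinary doubling runs until
all ranks are distinct.  For a collection of '$'-terminated short reads the
loop terminates after ~log2(read length / 16) doublings, which keeps desk-scale
collections (tens of Mbp) in the tens-of-seconds range on one core.
"""

from __future__ import annotations

import numpy as np


def suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array of a uint8 text over codes 0..4 ('$' sorts first).

    Ties between suffixes sharing a prefix (e.g. those reading through equal
    '$' symbols) are broken by full lexicographic comparison of the remainder
    of the concatenated text, which fixes a single canonical order.  Sort
    stability is not needed: rank assignment depends only on key equality,
    and the loop runs until every rank is unique.
    """
    t = np.asarray(text, dtype=np.uint8)
    n = t.size
    if n == 0:
        return np.empty(0, dtype=np.int32)
    if n == 1:
        return np.zeros(1, dtype=np.int32)
    pad = np.zeros(n + 16, dtype=np.int64)
    pad[:n] = t
    key = np.zeros(n, dtype=np.int64)
    for j in range(16):
        np.left_shift(key, 3, out=key)
        np.bitwise_or(key, pad[j : j + n], out=key)
    del pad
    order = np.argsort(key)
    kk = key[order]
    del key
    diff = np.empty(n, dtype=bool)
    diff[0] = True
    np.not_equal(kk[1:], kk[:-1], out=diff[1:])
    del kk
    # rank = index (in sorted order) of the first member of the suffix's
    # group; group-start semantics let later rounds renumber split groups
    # locally without touching resolved suffixes.  int32 throughout and
    # eager frees keep the working set bounded at desk scale.
    ar = np.arange(n, dtype=np.int32)
    rank = np.empty(n, dtype=np.int32)
    rank[order] = np.maximum.accumulate(np.where(diff, ar, 0))
    del order, diff, ar
    k = 16
    while True:
        counts = np.bincount(rank, minlength=n)
        tied = counts[rank] > 1
        del counts
        idx = np.flatnonzero(tied).astype(np.int32)
        del tied
        if idx.size == 0:
            break
        m = idx.size
        comb = rank[idx].astype(np.int64)
        comb *= np.int64(n + 1)
        ahead = idx.astype(np.int64)
        ahead += k
        valid = ahead < n
        comb[valid] += rank[ahead[valid]].astype(np.int64) + 1
        del ahead, valid
        o = np.argsort(comb).astype(np.int32)
        cc = comb[o]
        del comb
        sub = np.empty(m, dtype=bool)
        sub[0] = True
        np.not_equal(cc[1:], cc[:-1], out=sub[1:])
        del cc
        io = idx[o]
        del idx, o
        g = rank[io]
        am = np.arange(m, dtype=np.int32)
        sub_start = np.maximum.accumulate(np.where(sub, am, 0))
        run = np.empty(m, dtype=bool)
        run[0] = True
        np.not_equal(g[1:], g[:-1], out=run[1:])
        run_start = np.maximum.accumulate(np.where(run, am, 0))
        del am, sub, run
        rank[io] = g + (sub_start - run_start)
        del io, g, sub_start, run_start
        k *= 2
    # all groups are singletons: rank is a permutation of 0..n-1
    out = np.empty(n, dtype=np.int32)
    out[rank] = np.arange(n, dtype=np.int32)
    return out


def bwt_from_sa(text: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Burrows-Wheeler transform: preceding character of each sorted suffix
    (cyclically, so suffix 0 contributes the final character of the text)."""
    t = np.asarray(text, dtype=np.uint8)
    return t[(sa.astype(np.int64) - 1) % t.size].astype(np.uint8)


def lcp_array(text: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Longest-common-prefix array (Kasai); lcp[i] = LCP(sa[i-1], sa[i]),
    lcp[0] = 0.  Comparison stops at '$' boundaries implicitly because the
    sentinel mismatches every other symbol."""
    t = np.asarray(text, dtype=np.uint8)
    n = t.size
    sa = np.asarray(sa, dtype=np.int64)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    return _kasai(t, sa, rank)


def _kasai(t, sa, rank):  # pragma: no cover - exercised via lcp_array
    from ._kernels import kasai_kernel

    return kasai_kernel(t, sa, rank)
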