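"""Numba kernels: FM-index rank/backward-search, left-extension enumeration,
Kasai LCP, and Myers' bit-parallel semi-global edit distance.

All kernels operate on plain numpy arrays so they stay cache-friendly and can
be driven from the thin Python wrappers in :mod:`read_index` and
:mod:`breakpoint_scan`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BLOCK = 64  # occurrence checkpoint spacing (positions)


@njit(cache=True)
def kasai_kernel(t, sa, rank):
    n = t.size
    lcp = np.zeros(n, dtype=np.int32)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and t[i + h] == t[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


@njit(cache=True)
def build_checkpoints(bwt):
    n = bwt.size
    nblocks = n // BLOCK + 1
    ckpt = np.zeros((nblocks + 1, 5), dtype=np.int64)
    for i in range(n):
        ckpt[i // BLOCK + 1, bwt[i]] += 1
    # prefix-sum blocks: ckpt[b, c] = count of c in bwt[: b*BLOCK]
    for b in range(1, nblocks + 1):
        for c in range(5):
            ckpt[b, c] += ckpt[b - 1, c]
    return ckpt


@njit(inline="always")
def occ_rank(bwt, ckpt, c, p):
    """Number of occurrences of code c in bwt[:p]."""
    b = p // BLOCK
    cnt = ckpt[b, c]
    for i in range(b * BLOCK, p):
        if bwt[i] == c:
            cnt += 1
    return cnt


@njit(inline="always")
def backward_step_kernel(bwt, ckpt, cbase, lo, hi, c):
    nlo = cbase[c] + occ_rank(bwt, ckpt, c, lo)
    nhi = cbase[c] + occ_rank(bwt, ckpt, c, hi)
    return nlo, nhi


@njit(cache=True)
def count_pattern_kernel(bwt, ckpt, cbase, pat):
    lo = 0
    hi = bwt.size
    for k in range(pat.size - 1, -1, -1):
        lo, hi = backward_step_kernel(bwt, ckpt, cbase, lo, hi, pat[k])
        if lo >= hi:
            return 0
    return hi - lo


@njit(cache=True)
def match_interval_kernel(bwt, ckpt, cbase, pat):
    lo = 0
    hi = bwt.size
    for k in range(pat.size - 1, -1, -1):
        lo, hi = backward_step_kernel(bwt, ckpt, cbase, lo, hi, pat[k])
        if lo >= hi:
            return lo, lo
    return lo, hi


@njit(cache=True)
def enumerate_left_kernel(bwt, ckpt, cbase, lo0, hi0, ext_len, out_ext, out_len, out_sup):
    """DFS over A/C/G/T left extensions of the interval [lo0, hi0).

    Emits maximal extensions: depth == ext_len, or no base extends further.
    Returns the number of branches written (capped at out_ext.shape[0])."""
    cap = out_ext.shape[0]
    nout = 0
    # explicit stack: depth, lo, hi, next char to try (1..4)
    max_depth = ext_len
    st_lo = np.empty(max_depth + 1, dtype=np.int64)
    st_hi = np.empty(max_depth + 1, dtype=np.int64)
    st_c = np.empty(max_depth + 1, dtype=np.int64)
    st_live = np.empty(max_depth + 1, dtype=np.uint8)  # any child emitted/found
    path = np.empty(max_depth, dtype=np.uint8)
    depth = 0
    st_lo[0] = lo0
    st_hi[0] = hi0
    st_c[0] = 1
    st_live[0] = 0
    while depth >= 0:
        if depth == ext_len:
            if nout < cap:
                for j in range(depth):
                    out_ext[nout, j] = path[depth - 1 - j]
                out_len[nout] = depth
                out_sup[nout] = st_hi[depth] - st_lo[depth]
                nout += 1
            depth -= 1
            if depth >= 0:
                st_live[depth] = 1
            continue
        c = st_c[depth]
        if c > 4:
            if st_live[depth] == 0 and depth > 0:
                # dead end: no base extends further; emit the maximal extension
                if nout < cap:
                    for j in range(depth):
                        out_ext[nout, j] = path[depth - 1 - j]
                    out_len[nout] = depth
                    out_sup[nout] = st_hi[depth] - st_lo[depth]
                    nout += 1
            depth -= 1
            continue
        st_c[depth] = c + 1
        nlo, nhi = backward_step_kernel(bwt, ckpt, cbase, st_lo[depth], st_hi[depth], c)
        if nlo < nhi:
            st_live[depth] = 1
            path[depth] = np.uint8(c)
            depth += 1
            st_lo[depth] = nlo
            st_hi[depth] = nhi
            st_c[depth] = 1
            st_live[depth] = 0
    return nout


@njit(cache=True)
def myers_min_distance(pat, text):
    """Myers bit-parallel semi-global edit distance (pattern <= 64).

    Pattern must be fully consumed; text start and end are free — i.e. the
    minimum over substrings t of text of edit_distance(pat, t).  Returns
    (distance, end) where text[:end] is the prefix at which the minimum is
    attained (end of the best-matching substring)."""
    m = pat.size
    peq = np.zeros(5, dtype=np.uint64)
    one = np.uint64(1)
    for i in range(m):
        peq[pat[i]] |= one << np.uint64(i)
    vp = (one << np.uint64(m)) - one if m < 64 else np.uint64(0xFFFFFFFFFFFFFFFF)
    vn = np.uint64(0)
    score = m
    best = m
    best_end = 0
    mask = one << np.uint64(m - 1)
    for j in range(text.size):
        eq = peq[text[j]]
        x = eq | vn
        d0 = (((eq & vp) + vp) ^ vp) | x
        hp = vn | ~(d0 | vp)
        hn = vp & d0
        if hp & mask:
            score += 1
        elif hn & mask:
            score -= 1
        # search variant: the DP first column stays zero (free text start)
        hp = hp << one
        hn = hn << one
        vp = hn | ~(d0 | hp)
        vn = hp & d0
        if score < best:
            best = score
            best_end = j + 1
    return best, best_end


@njit(cache=True)
def dp_min_distance(pat, text):
    """Classic O(mn) semi-global DP; reference path for patterns > 64 symbols."""
    m = pat.size
    n = text.size
    prev = np.empty(n + 1, dtype=np.int64)
    cur = np.empty(n + 1, dtype=np.int64)
    for j in range(n + 1):
        prev[j] = 0
    for i in range(1, m + 1):
        cur[0] = i
        for j in range(1, n + 1):
            cost = 0 if pat[i - 1] == text[j - 1] else 1
            a = prev[j - 1] + cost
            b = prev[j] + 1
            c = cur[j - 1] + 1
            v = a if a < b else b
            if c < v:
                v = c
            cur[j] = v
        for j in range(n + 1):
            prev[j] = cur[j]
    best = prev[0]
    best_end = 0
    for j in range(1, n + 1):
        if prev[j] < best:
            best = prev[j]
            best_end = j
    return best, best_end
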