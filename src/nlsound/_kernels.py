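"""Numba inner loops for the quadratic-cost temporal estimators."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lz76_word_count(b: np.ndarray) -> int:
    """LZ76 exhaustive-history word count (Kaspar-Schuster scan).

    ``b`` is a uint8 0/1 array; the final, possibly incomplete word
    counts as one word.
    """
    n = b.size
    if n == 0:
        return 0
    if n == 1:
        return 1
    c = 1
    l = 1
    i = 0
    k = 1
    kmax = 1
    while True:
        if b[i + k - 1] == b[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > kmax:
                kmax = k
            i += 1
            if i == l:
                c += 1
                l += kmax
                if l + 1 > n:
                    break
                i = 0
                k = 1
                kmax = 1
            else:
                k = 1
    return c


@njit(cache=True)
def sampen_pair_counts(x: np.ndarray, m: int, r: float) -> tuple:
    """Unordered template-pair match counts (B at length m, A at m+1).

    Both template sets run over i = 0..n-m-1; matching is Chebyshev
    distance <= r with self-pairs excluded.
    """
    n = x.size
    nt = n - m
    a = 0
    b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            ok = True
            for d in range(m):
                if abs(x[i + d] - x[j + d]) > r:
                    ok = False
                    break
            if ok:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b
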