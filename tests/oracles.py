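"""Independent brute-force / closed-form oracles used by the tests.

Each function here is a literal transcription of the defining formula of
the quantity it checks, deliberately sharing no code with the package
implementation.
"""

from __future__ import annotations

import numpy as np


def lz76_substring_parser(bits) -> int:
    """Exhaustive-history LZ76 word count by direct substring search.

    Each word is extended until the candidate no longer occurs in the
    sequence up to (but excluding) the candidate's final symbol.
    """
    s = "".join("1" if int(v) else "0" for v in bits)
    n = len(s)
    c = 0
    i = 0
    while i < n:
        length = 1
        while i + length <= n and s[i:i + length] in s[: i + length - 1]:
            length += 1
        c += 1
        i += length
    return c


def sampen_bruteforce(x, m: int, r: float) -> float:
    """Sample entropy by explicit O(n^2) double-loop template counting."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + d] - x[j + d]) for d in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0:
        return float("inf")
    return -np.log(a / b)


def pe_histogram(x, order: int, delay: int, normalized: bool = True) -> float:
    """Permutation entropy by explicit pattern histogram (bits)."""
    x = np.asarray(x, dtype=float)
    counts: dict = {}
    for i in range(len(x) - (order - 1) * delay):
        window = x[i: i + order * delay: delay]
        pattern = tuple(np.argsort(window, kind="stable"))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    h = -sum((c / total) * np.log2(c / total) for c in counts.values())
    if normalized:
        import math

        h /= math.log2(math.factorial(order))
    return h


def pearson_formula(x, y) -> float:
    """Pearson r by the textbook covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def ols_normal_equations(X, y):
    """OLS with intercept via the normal equations; (beta, R^2)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    design = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    resid = y - design @ beta
    ss_res = (resid**2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return beta, 1.0 - ss_res / ss_tot


def anova_f_sums_of_squares(groups) -> float:
    """One-way ANOVA F by explicit between/within sums of squares."""
    grand = np.concatenate(groups).mean()
    k = len(groups)
    n = sum(len(g) for g in groups)
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum()
                    for g in groups)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def tukey_mean_diffs(groups):
    """All pairwise mean differences mean(b) - mean(a) for a < b."""
    from itertools import combinations

    means = [np.mean(g) for g in groups]
    return [means[j] - means[i]
            for i, j in combinations(range(len(groups)), 2)]


def ward_bruteforce(X):
    """Full Ward merge sequence by exhaustive pair search.

    Uses the size-weighted centroid formula
    d(A, B) = sqrt(2 |A||B| / (|A|+|B|)) * ||c_A - c_B||; returns a list
    of (leafset_a, leafset_b, height) in merge order.
    """
    X = np.asarray(X, float)
    n = len(X)
    clusters = {i: (frozenset([i]), X[i].copy(), 1) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                _, ca, na = clusters[a]
                _, cb, nb = clusters[b]
                d = np.sqrt(2 * na * nb / (na + nb)) * \
                    np.linalg.norm(ca - cb)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        sa, ca, na = clusters[a]
        sb, cb, nb = clusters[b]
        merges.append((sa, sb, d))
        del clusters[a], clusters[b]
        clusters[next_id] = (sa | sb, (na * ca + nb * cb) / (na + nb),
                             na + nb)
        next_id += 1
    return merges


def scipy_linkage_merge_sequence(X):
    """scipy Ward linkage expressed as (leafset_a, leafset_b, height)."""
    from scipy.cluster.hierarchy import linkage

    X = np.asarray(X, float)
    n = len(X)
    z = linkage(X, method="ward", metric="euclidean")
    sets = {i: frozenset([i]) for i in range(n)}
    out = []
    for row_i, (a, b, h, _) in enumerate(z):
        sa, sb = sets[int(a)], sets[int(b)]
        sets[n + row_i] = sa | sb
        out.append((sa, sb, float(h)))
    return out
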