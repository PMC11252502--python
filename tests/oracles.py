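"""Independent brute-force oracles used by the test suite.

These deliberately re-derive every quantity with plain loops and from-scratch
recomputation, sharing no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np


def average_ranks(values) -> list:
    """Average ranks (1 = smallest) computed by explicit tie grouping."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def tmm_factors_oracle(counts, trim_m=0.30, trim_a=0.05, weighted=True):
    """Literal step-by-step trimmed-mean-of-M-values factor computation.

    counts: 2-D array-like, genes x samples.  Returns a factor per sample,
    rescaled to geometric mean 1.
    """
    arr = np.asarray(counts, dtype=float)
    n_genes, n_samples = arr.shape
    N = [arr[:, k].sum() for k in range(n_samples)]
    cpm = np.empty_like(arr)
    for k in range(n_samples):
        cpm[:, k] = arr[:, k] / (N[k] / 1e6)
    q75 = [np.quantile(cpm[:, k], 0.75) for k in range(n_samples)]
    target = sum(q75) / n_samples
    ref = min(range(n_samples), key=lambda k: abs(q75[k] - target))

    factors = []
    for k in range(n_samples):
        if k == ref:
            factors.append(1.0)
            continue
        M, A, yk, yr = [], [], [], []
        for g in range(n_genes):
            if arr[g, k] > 0 and arr[g, ref] > 0:
                pk = arr[g, k] / N[k]
                pr = arr[g, ref] / N[ref]
                M.append(np.log2(pk / pr))
                A.append(0.5 * np.log2(pk * pr))
                yk.append(arr[g, k])
                yr.append(arr[g, ref])
        if not M:
            raise ValueError("no gene positive in both sample and reference")
        n = len(M)
        rM = average_ranks(M)
        rA = average_ranks(A)
        kept = [g for g in range(n)
                if trim_m <= rM[g] / (n + 1) <= 1 - trim_m
                and trim_a <= rA[g] / (n + 1) <= 1 - trim_a]
        if len(kept) < 10:
            factors.append(2.0 ** (sum(M) / n))
            continue
        if weighted:
            num = den = 0.0
            for g in kept:
                w = (N[k] - yk[g]) / (N[k] * yk[g]) + (N[ref] - yr[g]) / (N[ref] * yr[g])
                num += w * M[g]
                den += w
            factors.append(2.0 ** (num / den) if den > 0
                           else 2.0 ** (sum(M[g] for g in kept) / len(kept)))
        else:
            factors.append(2.0 ** (sum(M[g] for g in kept) / len(kept)))
    log_f = [np.log(f) for f in factors]
    gm = np.exp(sum(log_f) / n_samples)
    return [f / gm for f in factors]


def flatline_cutoff_oracle(sorted_vals, window, rel_tol) -> int:
    """Brute-force scan: smallest rank r (1-based) such that every successive
    decrement within ranks [r, r+window] is <= rel_tol * max; else n."""
    v = list(map(float, sorted_vals))
    n = len(v)
    tol = rel_tol * v[0]
    for r in range(1, n - window + 1):
        ok = True
        for i in range(r, r + window):  # pairs (i, i+1), 1-based
            if v[i - 1] - v[i] > tol:
                ok = False
                break
        if ok:
            return r
    return n


def agglomerate_oracle(values, k, linkage="average"):
    """Greedy agglomeration recomputing all inter-cluster distances from
    scratch at every step; ties broken by the lexicographically smallest pair
    of (smallest-member) indices.  Operates on the value-sorted order, like
    the implementation's documented contract.  Returns a partition of
    original indices as a set of frozensets.
    """
    idx = sorted(range(len(values)), key=lambda i: (values[i], i))
    clusters = [[i] for i in idx]

    def dist(a, b):
        pts_a = [values[i] for i in a]
        pts_b = [values[i] for i in b]
        ds = [abs(x - y) for x in pts_a for y in pts_b]
        if linkage == "average":
            return sum(ds) / len(ds)
        if linkage == "complete":
            return max(ds)
        # ward: SSE increase of merging, from scratch
        def sse(pts):
            m = sum(pts) / len(pts)
            return sum((x - m) ** 2 for x in pts)
        return sse(pts_a + pts_b) - sse(pts_a) - sse(pts_b)

    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = dist(clusters[a], clusters[b])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        _, a, b = best
        merged = clusters[a] + clusters[b]
        rest = [c for t, c in enumerate(clusters) if t not in (a, b)]
        clusters = rest + [merged]
        # keep clusters ordered by smallest member position in sorted order
        pos = {g: p for p, g in enumerate(idx)}
        clusters.sort(key=lambda c: min(pos[i] for i in c))
    return {frozenset(c) for c in clusters}


def shannon_oracle(values) -> float:
    total = sum(values)
    h = 0.0
    for v in values:
        if v > 0:
            p = v / total
            h -= p * np.log(p)
    return h
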