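"""Brute-force oracle implementations, independent of divscape internals."""

import numpy as np

def oracle_pairwise_diffs(calls):
    """Mean pairwise difference summed over sites, missing-aware, O(n^2)."""
    n_hap, n_sites = calls.shape
    total = 0.0
    for s in range(n_sites):
        col = calls[:, s]
        vals = col[col >= 0]
        n = len(vals)
        if n < 2:
            continue
        diffs = sum(1 for i in range(n) for j in range(i + 1, n)
                    if vals[i] != vals[j])
        total += diffs / (n * (n - 1) / 2)
    return total


def oracle_segregating_sites(calls):
    count = 0
    for s in range(calls.shape[1]):
        col = calls[:, s]
        vals = set(int(v) for v in col if v >= 0)
        if len(vals) >= 2:
            count += 1
    return count


def oracle_tajima_d(calls, n_hap):
    """Direct evaluation of the Tajima (1989) formulas."""
    import math

    S = oracle_segregating_sites(calls)
    if S == 0:
        return float("nan")
    pi = oracle_pairwise_diffs(calls)
    n = n_hap
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def oracle_spearman(x, y):
    """Rank-then-Pearson, written from the definition."""
    x, y = np.asarray(x, float), np.asarray(y, float)

    def rank(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1, dtype=float)
        # average ties
        for val in np.unique(v):
            sel = v == val
            r[sel] = r[sel].mean()
        return r

    rx, ry = rank(x), rank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


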