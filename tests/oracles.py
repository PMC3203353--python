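"""Independent brute-force oracles used to validate the fast implementations.

Each oracle deliberately re-derives its answer from first principles —
literal 1 bp window sliding, exhaustive hypergeometric enumeration, full
partition enumeration with adaptive quadrature — and shares no code path
with the routines it checks.
"""

from itertools import product

import numpy as np
from scipy.integrate import quad
from scipy.special import betainc, betaln
from scipy.stats import hypergeom


def sliding_window_cis(positions, rules):
    """Literal 1 bp sliding-window CIS scan on one chromosome.

    Slides a half-open window [a, a+w) one bp at a time over the full
    span and collects, for every window holding >= y VIS, the interval
    between its outermost member VIS.  Overlapping/book-ended intervals
    are merged.  Only usable on small spans.
    """
    positions = np.asarray(sorted(positions))
    if len(positions) == 0:
        return []
    intervals = []
    lo, hi = int(positions.min()), int(positions.max())
    for window, min_count in rules:
        for a in range(max(lo - window, 0), hi + 1):
            inside = positions[(positions >= a) & (positions < a + window)]
            if len(inside) >= min_count:
                intervals.append((int(inside.min()), int(inside.max())))
    if not intervals:
        return []
    intervals.sort()
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def fisher_two_sided(table):
    """Two-sided Fisher exact p by exhaustive enumeration.

    Sums hypergeometric point probabilities not exceeding the observed
    table's (with R's 1+1e-7 relative tolerance for ties).
    """
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = hypergeom(n, row1, col1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = rv.pmf(support)
    observed = rv.pmf(a)
    return float(probs[probs <= observed * (1 + 1e-7)].sum())


def bcp_enumeration(x, p0=0.2, w0=0.2):
    """Exact change-point posterior by enumerating all 2^(n-1) partitions.

    The w-integrals are evaluated with adaptive quadrature, independent of
    the incomplete-beta forms used by the sampler.  Returns (posterior
    means, change probabilities).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    xbar = x.mean()

    def log_p_part(c):
        a, b = c + 1.0, n - c
        return betaln(a, b) + np.log(betainc(a, b, p0))

    def j_int(c, W, B, extra=0.0):
        f = lambda w: w ** (c / 2.0 + extra) * (W + w * B) ** (-(n - 1) / 2.0)
        val, _ = quad(f, 0.0, w0, epsrel=1e-11, limit=200)
        return val

    log_weights, mus, rhos = [], [], []
    for rho in product((0, 1), repeat=n - 1):
        edges = [0] + [i + 1 for i, r in enumerate(rho) if r] + [n]
        c = sum(rho)
        W = sum(
            float(((x[l:r] - x[l:r].mean()) ** 2).sum())
            for l, r in zip(edges[:-1], edges[1:])
        )
        B = sum(
            (r - l) * (x[l:r].mean() - xbar) ** 2
            for l, r in zip(edges[:-1], edges[1:])
        )
        j0 = j_int(c, W, B)
        what = min(j_int(c, W, B, extra=1.0) / j0, w0)
        mu = np.empty(n)
        for l, r in zip(edges[:-1], edges[1:]):
            mu[l:r] = xbar + (1.0 - what) * (x[l:r].mean() - xbar)
        log_weights.append(log_p_part(c) + np.log(j0))
        mus.append(mu)
        rhos.append(np.asarray(rho, dtype=float))
    log_weights = np.asarray(log_weights)
    w = np.exp(log_weights - log_weights.max())
    w /= w.sum()
    mu_post = np.einsum("k,kn->n", w, np.asarray(mus))
    p_post = np.einsum("k,kn->n", w, np.asarray(rhos))
    return mu_post, p_post


def brute_force_bin_assignment(chrom_idx, positions, partition):
    """Assign each VIS to a bin by linear search over all bins."""
    counts = np.zeros(partition.n, dtype=int)
    names_ci = partition.bin_chrom
    for ci, pos in zip(chrom_idx, positions):
        for b in range(partition.n):
            if (
                names_ci[b] == ci
                and partition.bin_start[b] < pos <= partition.bin_end[b]
            ):
                counts[b] += 1
                break
        else:
            raise AssertionError("position not covered by any bin")
    return counts


def interval_overlap_count(intervals, start0, end0):
    """Brute-force count of intervals overlapping [start0, end0) by >=1 bp."""
    return sum(1 for s, e in intervals if s < end0 and e > start0)
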