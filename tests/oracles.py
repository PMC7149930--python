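"""Independent brute-force reference implementations used only by the tests.

Everything here is written as naive loops over the definitions, deliberately
avoiding the vectorised code paths of the package so that agreement between
the two is a meaningful check.
"""

from __future__ import annotations

import math


def window_sums(intervals, n, m):
    """Composite intervals by explicit window enumeration."""
    out = []
    k = 0
    while k * m + n <= len(intervals):
        out.append(sum(intervals[k * m + j] for j in range(n)))
        k += 1
    return out


def naive_mean(x):
    return sum(x) / len(x)


def naive_sd(x, sample=True):
    mu = naive_mean(x)
    ss = sum((v - mu) ** 2 for v in x)
    return math.sqrt(ss / (len(x) - 1 if sample else len(x)))


def naive_rmssd(x):
    diffs = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    return math.sqrt(sum(d * d for d in diffs) / len(diffs))


def naive_moments(x):
    """(skewness, Pearson kurtosis) by direct central-moment sums."""
    mu = naive_mean(x)
    n = len(x)
    m2 = sum((v - mu) ** 2 for v in x) / n
    m3 = sum((v - mu) ** 3 for v in x) / n
    m4 = sum((v - mu) ** 4 for v in x) / n
    return m3 / m2**1.5, m4 / m2**2


def naive_nn50(x, threshold):
    return sum(1 for i in range(len(x) - 1) if abs(x[i + 1] - x[i]) > threshold)


def naive_triangular_index(x, bin_width):
    counts: dict[int, int] = {}
    for v in x:
        b = math.floor(v / bin_width)
        counts[b] = counts.get(b, 0) + 1
    return len(x) / max(counts.values())


def _cheb(a, b):
    return max(abs(u - v) for u, v in zip(a, b))


def naive_sampen(x, m=2, r=None, r_frac=0.2):
    """Sample entropy by explicit pairwise template counting (self excluded)."""
    if r is None:
        r = r_frac * naive_sd(x, sample=False)
    N = len(x)
    K = N - m
    A = B = 0
    for i in range(K):
        for j in range(K):
            if i == j:
                continue
            if _cheb(x[i:i + m], x[j:j + m]) <= r:
                B += 1
            if _cheb(x[i:i + m + 1], x[j:j + m + 1]) <= r:
                A += 1
    if A == 0 or B == 0:
        return math.nan
    return -math.log(A / B)


def naive_apen(x, m=2, r=None, r_frac=0.2):
    """Approximate entropy by explicit counting (self-matches included)."""
    if r is None:
        r = r_frac * naive_sd(x, sample=False)
    N = len(x)

    def phi(mm):
        K = N - mm + 1
        total = 0.0
        for i in range(K):
            c = sum(
                1 for j in range(K) if _cheb(x[i:i + mm], x[j:j + mm]) <= r
            )
            total += math.log(c / K)
        return total / K

    return phi(m) - phi(m + 1)


def poincare_rotation(x):
    """(SD1, SD2) from the rotated lag-1 scatter, axes at 45 degrees.

    The transverse coordinate is taken about zero (its mean is the
    negligible drift term), the longitudinal one about its mean; population
    normalisation.
    """
    pts = [(x[i], x[i + 1]) for i in range(len(x) - 1)]
    s2 = math.sqrt(2.0)
    u = [(b - a) / s2 for a, b in pts]   # perpendicular to identity line
    v = [(a + b) / s2 for a, b in pts]   # along identity line
    sd1 = math.sqrt(sum(w * w for w in u) / len(u))
    vm = naive_mean(v)
    sd2 = math.sqrt(sum((w - vm) ** 2 for w in v) / len(v))
    return sd1, sd2


def pair_count_auc(scores, outcome):
    """Mann-Whitney concordance: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, outcome) if y == 1]
    neg = [s for s, y in zip(scores, outcome) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
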