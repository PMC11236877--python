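"""Naive, loop-based transcriptions of the seven canonical time-series
statistics, used as an independent oracle for the package's vectorized
implementations.

Each function follows its published definition literally: autocorrelations
are direct O(n^2) lag sums, symbolizations use explicit dictionaries, and the
outlier-inclusion statistic recomputes the event set from scratch at every
threshold.  Slow by construction; run only on short fixtures.
"""

import math

import numpy as np


def zscore(y):
    y = np.asarray(y, dtype=float)
    return (y - y.mean()) / y.std()


def acf_direct(z, lag):
    """Biased autocorrelation at one lag, direct sum."""
    n = len(z)
    x = z - z.mean()
    num = sum(x[i] * x[i + lag] for i in range(n - lag))
    den = sum(xi * xi for xi in x)
    return num / den


def f1ecac(y):
    z = zscore(y)
    thresh = 1.0 / math.e
    prev = acf_direct(z, 0)
    for lag in range(1, len(z)):
        cur = acf_direct(z, lag)
        if cur < thresh:
            return (lag - 1) + (thresh - prev) / (cur - prev)
        prev = cur
    return float(len(z))


def first_min_ac(y):
    z = zscore(y)
    ac = [acf_direct(z, lag) for lag in range(len(z))]
    for i in range(1, len(ac) - 1):
        if ac[i] < ac[i - 1] and ac[i] < ac[i + 1]:
            return float(i)
    return float(len(ac))


def pnn40(y):
    z = zscore(y)
    exceed = 0
    for i in range(len(z) - 1):
        if abs(z[i + 1] - z[i]) > 0.04:
            exceed += 1
    return exceed / (len(z) - 1)


def longstretch_decreases(y):
    z = zscore(y)
    longest = cur = 0
    for i in range(len(z) - 1):
        if z[i + 1] - z[i] < 0:
            cur += 1
            longest = max(longest, cur)
        else:
            cur = 0
    return float(longest)


def motif_three_hh(y):
    z = zscore(y)
    q1 = np.quantile(z, 1.0 / 3.0)
    q2 = np.quantile(z, 2.0 / 3.0)
    letters = []
    for v in z:
        if v <= q1:
            letters.append("a")
        elif v <= q2:
            letters.append("b")
        else:
            letters.append("c")
    counts = {}
    for a, b in zip(letters[:-1], letters[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    total = sum(counts.values())
    h = 0.0
    for c in counts.values():
        p = c / total
        h -= p * math.log(p)
    return h


def outlier_include_mdrmd(y, sign):
    z = zscore(y)
    if sign < 0:
        z = -z
    n = len(z)
    inc = 0.01
    ymax = z.max()
    if ymax < 0:
        return 0.0
    msDti3, msDti4 = [], []
    for j in range(int(ymax / inc) + 1):
        th = j * inc
        events = [i for i in range(n) if z[i] >= th]
        msDti3.append((len(events) - 1) * 100.0 / n if events else 0.0)
        med = float(np.median(events)) if events else 0.0
        msDti4.append(med / (n / 2.0) - 1.0 if events else 0.0)
        th += inc
    last = None
    for j, v in enumerate(msDti3):
        if v > 2.0:
            last = j
    if last is None:
        return 0.0
    return float(np.median(msDti4[: last + 1]))


def catch7_naive(y):
    return np.array(
        [
            f1ecac(y),
            first_min_ac(y),
            pnn40(y),
            outlier_include_mdrmd(y, +1),
            outlier_include_mdrmd(y, -1),
            longstretch_decreases(y),
            motif_three_hh(y),
        ]
    )
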