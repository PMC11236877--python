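"""The seven canonical time-series statistics used by the sector classifier.

These are the Catch-22 features named in the model's feature schema,
implemented here because no reference package is available in the runtime
environment: two linear-autocorrelation features (CO_f1ecac, CO_FirstMin_ac),
three successive-difference / symbolic features (MD_hrv_classic_pnn40,
SB_BinaryStats_diff_longstretch0, SB_MotifThree_quantile_hh) and the two
outlier-inclusion temporal statistics (DN_OutlierInclude_{p,n}_001_mdrmd).

Convention: every statistic operates on the z-scored series (the canonical
definition; e.g. pNN40 thresholds successive differences at 0.04 sigma).
A constant (zero-variance) input cannot be z-scored; every feature then
returns the sentinel 0.0.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CATCH22_NAMES",
    "co_f1ecac",
    "co_first_min_ac",
    "md_hrv_classic_pnn40",
    "sb_binarystats_diff_longstretch0",
    "sb_motifthree_quantile_hh",
    "dn_outlierinclude_p_001_mdrmd",
    "dn_outlierinclude_n_001_mdrmd",
    "catch7",
]

CATCH22_NAMES = (
    "CO_f1ecac",
    "CO_FirstMin_ac",
    "MD_hrv_classic_pnn40",
    "DN_OutlierInclude_p_001_mdrmd",
    "DN_OutlierInclude_n_001_mdrmd",
    "SB_BinaryStats_diff_longstretch0",
    "SB_MotifThree_quantile_hh",
)


def _zscore(y: np.ndarray):
    y = np.asarray(y, dtype=float)
    sd = y.std()
    # ptp guards exact constants whose float std is a rounding residue
    if sd == 0 or not np.isfinite(sd) or np.ptp(y) == 0:
        return None
    return (y - y.mean()) / sd


def _autocorr(y: np.ndarray) -> np.ndarray:
    """Normalized autocorrelation function via FFT (biased estimator)."""
    n = len(y)
    x = y - y.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(f * f.conj(), nfft)[:n]
    if ac[0] == 0:
        return np.zeros(n)
    return ac / ac[0]


def co_f1ecac(y) -> float:
    """First 1/e crossing of the autocorrelation function, linearly
    interpolated between lags; returns the series length if the ACF never
    drops below 1/e."""
    z = _zscore(y)
    if z is None:
        return 0.0
    ac = _autocorr(z)
    thresh = 1.0 / np.e
    for i in range(len(ac) - 1):
        if ac[i + 1] < thresh:
            return float(i + (thresh - ac[i]) / (ac[i + 1] - ac[i]))
    return float(len(ac))


def co_first_min_ac(y) -> float:
    """Lag of the first local minimum of the autocorrelation function."""
    z = _zscore(y)
    if z is None:
        return 0.0
    ac = _autocorr(z)
    for i in range(1, len(ac) - 1):
        if ac[i] < ac[i - 1] and ac[i] < ac[i + 1]:
            return float(i)
    return float(len(ac))


def md_hrv_classic_pnn40(y) -> float:
    """Proportion of successive differences exceeding 0.04 sigma."""
    z = _zscore(y)
    if z is None:
        return 0.0
    d = np.abs(np.diff(z))
    return float(np.mean(d > 0.04))


def sb_binarystats_diff_longstretch0(y) -> float:
    """Longest run of successive decreases (diff binarized at zero, longest
    stretch of the 'decrease' symbol)."""
    z = _zscore(y)
    if z is None:
        return 0.0
    b = np.diff(z) >= 0  # False marks a decrease
    longest = cur = 0
    for v in b:
        if not v:
            cur += 1
            longest = max(longest, cur)
        else:
            cur = 0
    return float(longest)


def sb_motifthree_quantile_hh(y) -> float:
    """Shannon entropy (nats) of successive letter pairs after equiprobable
    3-letter quantile symbolization."""
    z = _zscore(y)
    if z is None:
        return 0.0
    q1, q2 = np.quantile(z, [1.0 / 3.0, 2.0 / 3.0])
    sym = np.digitize(z, [q1, q2], right=True)  # 0, 1, 2 (boundaries bind down)
    pairs = sym[:-1] * 3 + sym[1:]
    counts = np.bincount(pairs, minlength=9).astype(float)
    p = counts / counts.sum()
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def _outlier_include_mdrmd(z: np.ndarray, inc: float = 0.01, trim_percent: float = 2.0) -> float:
    """Median (over inclusion thresholds) of the median timing of extreme
    events above successive thresholds, timing normalized to [-1, 1].

    Thresholds run 0, inc, 2*inc, ... up to the series maximum; for each, the
    events are samples >= threshold, their median index is mapped to
    (median/(N/2) - 1), and thresholds are kept while events-per-sample stays
    above ``trim_percent`` percent.
    """
    n = len(z)
    ymax = z.max()
    if ymax < 0:
        return 0.0
    n_thresh = int(ymax / inc) + 1
    # order sample positions by descending value: threshold j keeps a prefix
    order = np.argsort(-z, kind="stable")
    pos_by_rank = order.astype(float)
    # prefix medians via incremental insertion into a sorted list
    import bisect

    sorted_prefix: list[float] = []
    prefix_median = np.empty(n)
    for i, p in enumerate(pos_by_rank):
        bisect.insort(sorted_prefix, p)
        m = len(sorted_prefix)
        if m % 2:
            prefix_median[i] = sorted_prefix[m // 2]
        else:
            prefix_median[i] = 0.5 * (sorted_prefix[m // 2 - 1] + sorted_prefix[m // 2])
    zs = z[order]  # descending values
    msDti3 = np.empty(n_thresh)
    msDti4 = np.empty(n_thresh)
    for j in range(n_thresh):
        th = j * inc
        c = int(np.searchsorted(-zs, -th, side="right"))  # count of z >= th
        if c == 0:
            msDti3[j] = 0.0
            msDti4[j] = 0.0
            continue
        msDti3[j] = (c - 1) * 100.0 / n
        msDti4[j] = prefix_median[c - 1] / (n / 2.0) - 1.0
    keep = np.nonzero(msDti3 > trim_percent)[0]
    if keep.size == 0:
        return 0.0
    last = keep[-1]
    return float(np.median(msDti4[: last + 1]))


def dn_outlierinclude_p_001_mdrmd(y) -> float:
    """Outlier-inclusion timing statistic for extreme events above the mean."""
    z = _zscore(y)
    if z is None:
        return 0.0
    return _outlier_include_mdrmd(z)


def dn_outlierinclude_n_001_mdrmd(y) -> float:
    """Same as the positive variant, on the sign-flipped series (extreme
    events below the mean)."""
    z = _zscore(y)
    if z is None:
        return 0.0
    return _outlier_include_mdrmd(-z)


_FUNCS = {
    "CO_f1ecac": co_f1ecac,
    "CO_FirstMin_ac": co_first_min_ac,
    "MD_hrv_classic_pnn40": md_hrv_classic_pnn40,
    "DN_OutlierInclude_p_001_mdrmd": dn_outlierinclude_p_001_mdrmd,
    "DN_OutlierInclude_n_001_mdrmd": dn_outlierinclude_n_001_mdrmd,
    "SB_BinaryStats_diff_longstretch0": sb_binarystats_diff_longstretch0,
    "SB_MotifThree_quantile_hh": sb_motifthree_quantile_hh,
}


def catch7(y, names=CATCH22_NAMES) -> np.ndarray:
    """All seven statistics of one series, in canonical order."""
    return np.array([_FUNCS[n](y) for n in names])
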