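"""The 19-element feature vector computed from one optimized sector response.

Twelve custom waveform/frequency statistics plus seven canonical time-series
(Catch-22) statistics, all on the 500 ms / 1 kHz decoded waveform.  Feature
definitions reference filtered views of the signal: BP = band-pass 3–50 Hz,
LP f / HP f = low/high-pass with corner f; every per-feature filter is a
4th-order Bessel applied forward-backward (zero phase).  Window bounds are
milliseconds.

The discriminative idea: sectors the subject cannot see produce responses
dominated by intrinsic alpha rhythm (8–13 Hz) and noise, so features contrast
early-window structure against the late window, correlate against a canonical
normal response, and quantify alpha-band dominance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.stats import skew

from ._catch22 import (
    co_f1ecac,
    co_first_min_ac,
    dn_outlierinclude_n_001_mdrmd,
    dn_outlierinclude_p_001_mdrmd,
    md_hrv_classic_pnn40,
    sb_binarystats_diff_longstretch0,
    sb_motifthree_quantile_hh,
)
from ._wavelets import dwt_approx_coeffs

__all__ = [
    "FEATURE_NAMES",
    "CUSTOM_FEATURE_NAMES",
    "CATCH22_FEATURE_NAMES",
    "ReferenceTemplate",
    "compute_custom_features",
    "compute_catch22_features",
    "extract_features",
    "extract_feature_matrix",
]

CUSTOM_FEATURE_NAMES = (
    "sig_snr",
    "sig_hp_cor",
    "response_cor",
    "std_ratio",
    "mid_abs_auc_ratio",
    "skewness",
    "peak_amp_ratio_13",
    "peak_amp_ratio_14",
    "no_zero_x",
    "fft_resp_to_alpha_power",
    "wv_apprx_std_0",
    "wv_apprx_std_1",
)
CATCH22_FEATURE_NAMES = (
    "CO_f1ecac",
    "CO_FirstMin_ac",
    "MD_hrv_classic_pnn40",
    "DN_OutlierInclude_p_001_mdrmd",
    "DN_OutlierInclude_n_001_mdrmd",
    "SB_BinaryStats_diff_longstretch0",
    "SB_MotifThree_quantile_hh",
)
FEATURE_NAMES = CUSTOM_FEATURE_NAMES + CATCH22_FEATURE_NAMES

RATE_HZ = 1000.0


@dataclass
class ReferenceTemplate:
    """Canonical normal response over 0–200 ms, correlated against incoming
    responses (feature ``response_cor``).  Built as the mean of a training
    set's normal-labeled responses; stored with the trained model."""

    waveform: np.ndarray  # 200 samples
    provenance: str = ""

    @staticmethod
    def from_normals(responses: np.ndarray, provenance: str = "mean of normal training responses"):
        return ReferenceTemplate(
            waveform=np.asarray(responses, dtype=float)[:, :200].mean(axis=0),
            provenance=provenance,
        )


def _bessel(x: np.ndarray, btype: str, corner, order: int = 4) -> np.ndarray:
    sos = sps.bessel(order, corner, btype=btype, fs=RATE_HZ, output="sos", norm="mag")
    return sps.sosfiltfilt(sos, x, axis=-1)


def _views(x: np.ndarray) -> dict:
    """All filtered views the Table-2 definitions reference (batched)."""
    return {
        "bp": _bessel(x, "bandpass", (3.0, 50.0)),
        "lp20": _bessel(x, "lowpass", 20.0),
        "lp9": _bessel(x, "lowpass", 9.0),
        "hp9": _bessel(x, "highpass", 9.0),
        "hp20": _bessel(x, "highpass", 20.0),
    }


def _corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of (n, t) against (n, t) or (t,)."""
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    den = np.sqrt((a**2).sum(axis=-1) * (b**2).sum(axis=-1))
    num = (a * b).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _ranked_peak_ratio(x: np.ndarray, rank: int, min_sep_samples: int = 10):
    """|highest peak| / |rank-th highest peak| over local extrema of either
    sign with a minimum separation; falls back to the lowest-ranked available
    peak (flagged) when fewer exist."""
    pos, _ = sps.find_peaks(x, distance=min_sep_samples)
    neg, _ = sps.find_peaks(-x, distance=min_sep_samples)
    amps = np.sort(np.abs(np.concatenate([x[pos], x[neg]])))[::-1]
    if amps.size == 0 or amps[0] == 0:
        return 0.0, True
    k = min(rank, amps.size) - 1
    flagged = amps.size < rank or amps[k] == 0
    denom = amps[k] if amps[k] > 0 else amps[amps > 0][-1] if (amps > 0).any() else 1.0
    return float(amps[0] / denom), flagged


def _std(x: np.ndarray, axis=-1) -> np.ndarray:
    return np.asarray(x).std(axis=axis)


def compute_custom_features(
    response: np.ndarray, reference: ReferenceTemplate
) -> np.ndarray:
    """The 12 custom statistics of one 500 ms response, in canonical order.
    Non-finite values (zero-variance windows) map to 0."""
    return _custom_matrix(np.asarray(response, dtype=float)[None, :], reference)[0]


def _custom_matrix(x: np.ndarray, reference: ReferenceTemplate) -> np.ndarray:
    if x.shape[-1] != 500:
        raise ValueError("responses must be 500 samples (500 ms at 1 kHz)")
    v = _views(x)
    n = x.shape[0]
    out = np.empty((n, 12))
    with np.errstate(invalid="ignore", divide="ignore"):
        out[:, 0] = _std(v["lp20"][:, 50:200]) / _std(v["lp20"][:, 250:500])
        out[:, 1] = _corr(v["bp"], v["hp9"])
        out[:, 2] = _corr(v["lp20"][:, :200], reference.waveform)
        out[:, 3] = _std(v["bp"][:, :250]) / _std(v["hp20"][:, 250:500])
        out[:, 4] = np.trapezoid(np.abs(v["lp20"][:, :250]), axis=-1) / np.trapezoid(
            np.abs(v["lp20"][:, 250:500]), axis=-1
        )
        import warnings

        with warnings.catch_warnings():
            # constant rows hit scipy's catastrophic-cancellation warning;
            # their non-finite skew maps to the 0 sentinel below
            warnings.simplefilter("ignore", RuntimeWarning)
            out[:, 5] = skew(v["lp9"], axis=-1)
    for i in range(n):
        out[i, 6], _ = _ranked_peak_ratio(v["bp"][i], 3)
        out[i, 7], _ = _ranked_peak_ratio(v["bp"][i], 4)
    sgn = np.sign(v["bp"])
    out[:, 8] = ((sgn[:, 1:] * sgn[:, :-1]) < 0).sum(axis=-1)
    P = np.abs(np.fft.rfft(v["bp"], axis=-1)) ** 2
    freqs = np.fft.rfftfreq(500, d=1.0 / RATE_HZ)
    alpha = (freqs >= 8.0) & (freqs <= 13.0)
    low = freqs < 8.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out[:, 9] = P[:, alpha].max(axis=-1) / P[:, low].max(axis=-1)
    a1 = dwt_approx_coeffs(v["bp"], 1)
    a2 = dwt_approx_coeffs(v["bp"], 2)
    out[:, 10] = _std(a1[:, : a1.shape[1] // 2])
    out[:, 11] = _std(a2[:, : a2.shape[1] // 2])
    out[~np.isfinite(out)] = 0.0
    return out


def compute_catch22_features(response: np.ndarray) -> np.ndarray:
    """The 7 canonical time-series statistics: all on the band-passed
    (3–50 Hz) 0–500 ms signal except SB_MotifThree_quantile_hh, which uses
    the 50–200 ms slice."""
    return _catch22_matrix(np.asarray(response, dtype=float)[None, :])[0]


def _catch22_matrix(x: np.ndarray) -> np.ndarray:
    bp = _bessel(x, "bandpass", (3.0, 50.0))
    n = x.shape[0]
    out = np.empty((n, 7))
    for i in range(n):
        y = bp[i]
        out[i, 0] = co_f1ecac(y)
        out[i, 1] = co_first_min_ac(y)
        out[i, 2] = md_hrv_classic_pnn40(y)
        out[i, 3] = dn_outlierinclude_p_001_mdrmd(y)
        out[i, 4] = dn_outlierinclude_n_001_mdrmd(y)
        out[i, 5] = sb_binarystats_diff_longstretch0(y)
        out[i, 6] = sb_motifthree_quantile_hh(y[50:200])
    out[~np.isfinite(out)] = 0.0
    return out


def extract_features(response: np.ndarray, reference: ReferenceTemplate) -> np.ndarray:
    """Full 19-element feature vector (custom then Catch-22, canonical
    order); deterministic."""
    return np.concatenate(
        [compute_custom_features(response, reference), compute_catch22_features(response)]
    )


def extract_feature_matrix(responses: np.ndarray, reference: ReferenceTemplate) -> np.ndarray:
    """Feature vectors for a batch of responses, shape (n, 19).  Filters and
    spectra are computed batched; equals row-wise :func:`extract_features`."""
    x = np.asarray(responses, dtype=float)
    return np.hstack([_custom_matrix(x, reference), _catch22_matrix(x)])
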