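"""Minimal stationary/discrete wavelet machinery (symlet-4).

Only what the pipeline needs: the undecimated (stationary) wavelet transform's
approximation projection — used as a zero-phase baseline estimator and
low-pass filter — and plain DWT approximation coefficients for two feature
statistics.

The SWT approximation-at-depth-d projection is realized in the frequency
domain: analysis with the dilated scaling filter followed by synthesis with
its conjugate gives the per-level transfer |H_j(w)|^2 / 2, and the depth-d
approximation reconstruction is the product over levels j = 0..d-1.  For an
orthonormal filter pair |H|^2 + |G|^2 = 2, so dropping the details and
applying this product is exactly the shift-invariant SWT low-pass with zero
phase.  Signals are reflect-padded before the circular convolution to keep
boundary wrap-around out of the analysis window.
"""

from __future__ import annotations

import numpy as np

# Symlet-4 decomposition low-pass taps (orthonormal, sum = sqrt(2)).
SYM4_DEC_LO = np.array(
    [
        -0.07576571478927333,
        -0.02963552764599851,
        0.49761866763201545,
        0.8037387518059161,
        0.29785779560527736,
        -0.09921954357684722,
        -0.012603967262037833,
        0.0322231006040427,
    ]
)


def _swt_approx_transfer(n: int, depth: int, dec_lo: np.ndarray) -> np.ndarray:
    """Transfer function (rfft bins, length n) of the depth-`depth` SWT
    approximation projection."""
    w = 2.0 * np.pi * np.fft.rfftfreq(n)
    T = np.ones_like(w)
    k = np.arange(len(dec_lo))
    for j in range(depth):
        H = np.exp(-1j * np.outer(w, k * 2**j)) @ dec_lo
        T *= np.abs(H) ** 2 / 2.0
    return T


def swt_approximation(signal: np.ndarray, depth: int, dec_lo: np.ndarray = SYM4_DEC_LO) -> np.ndarray:
    """Depth-``depth`` SWT approximation (low-pass) of ``signal`` along the
    last axis; zero-phase and shift-invariant.  Works on 1-D or 2-D input."""
    x = np.asarray(signal, dtype=float)
    n = x.shape[-1]
    pad = min(n, 2 ** (depth + 3))
    xp = np.concatenate([x[..., pad - 1 :: -1], x, x[..., : -pad - 1 : -1]], axis=-1)
    m = xp.shape[-1]
    T = _swt_approx_transfer(m, depth, dec_lo)
    out = np.fft.irfft(np.fft.rfft(xp, axis=-1) * T, m, axis=-1)
    return out[..., pad : pad + n]


def swt_depth_for_cutoff(rate_hz: float, cutoff_hz: float) -> int:
    """Decomposition depth whose approximation band edge sits at ~cutoff:
    depth = floor(log2(rate / cutoff)) - 1."""
    if cutoff_hz <= 0 or cutoff_hz >= rate_hz / 2:
        raise ValueError("cutoff must lie in (0, rate/2)")
    return max(1, int(np.floor(np.log2(rate_hz / cutoff_hz))) - 1)


def dwt_approx_coeffs(signal: np.ndarray, level: int, dec_lo: np.ndarray = SYM4_DEC_LO) -> np.ndarray:
    """Approximation coefficients of a plain decimated DWT at ``level``
    (symmetric boundary extension), along the last axis of 1-D/2-D input."""
    a = np.asarray(signal, dtype=float)
    L = len(dec_lo)
    for _ in range(level):
        pad = L - 1
        ap = np.concatenate([a[..., pad - 1 :: -1], a, a[..., : -pad - 1 : -1]], axis=-1)
        # correlate with dec_lo then downsample by 2 (standard analysis step)
        n_out = (a.shape[-1] + L - 1) // 2
        idx = 2 * np.arange(n_out)[:, None] + np.arange(L)[None, :]
        idx = np.clip(idx, 0, ap.shape[-1] - 1)
        a = np.einsum("...nk,k->...n", ap[..., idx], dec_lo[::-1])
    return a
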