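"""Orthogonal discrete wavelet transform with periodic boundary handling.

Self-contained single-axis DWT used by :mod:`otloc.preprocess`.  The filter
bank is expressed through the decomposition low-pass filter; the high-pass
and synthesis filters follow from the standard quadrature-mirror relations,
so perfect reconstruction holds to machine precision for any orthonormal
filter (verified by the test suite).
"""

from __future__ import annotations

import numpy as np

from .errors import BadWaveletError, TooShortError

# coif5 decomposition low-pass filter (30 taps, orthonormal).
_COIF5_DEC_LO = np.array([
    -9.604010112767894e-08,
    -1.6237995172048338e-07,
    2.0612203985788783e-06,
    3.7007277113394796e-06,
    -2.1270221672515614e-05,
    -4.12198619242655e-05,
    0.00014035632812373243,
    0.0003018579416682448,
    -0.0006375589261258812,
    -0.0016616273039298788,
    0.0024315754425382886,
    0.006761520220620417,
    -0.009159507338676163,
    -0.019758391600965465,
    0.032674799467057355,
    0.041287530472117834,
    -0.10556315130733723,
    -0.06203775157498196,
    0.4379823066591634,
    0.7742936228603274,
    0.42157126673075435,
    -0.052046670253554764,
    -0.09192158806008609,
    0.028169744270532353,
    0.023408322118927783,
    -0.010131584846900276,
    -0.00415931262757864,
    0.0021782943778456947,
    0.0003585777411617577,
    -0.000212081862067494,
])

# db4 kept as a secondary option for experimentation.
_DB4_DEC_LO = np.array([
    -0.010597401784997278,
    0.032883011666982945,
    0.030841381835986965,
    -0.18703481171888114,
    -0.02798376941698385,
    0.6308807679295904,
    0.7148465705525415,
    0.23037781330885523,
])

FILTER_BANK: dict[str, np.ndarray] = {
    "coif5": _COIF5_DEC_LO,
    "db4": _DB4_DEC_LO,
}


def _filters(name: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        lo = FILTER_BANK[name]
    except KeyError:
        raise BadWaveletError(f"unknown wavelet {name!r}") from None
    hi = (lo[::-1] * np.cumprod(np.full(len(lo), -1)) * -1)  # (-1)^k lo[N-1-k]
    return lo, hi


def _wrap(x: np.ndarray, count: int) -> np.ndarray:
    """The last/first ``count`` samples of the periodic extension of ``x``."""
    reps = int(np.ceil(count / x.size))
    return np.tile(x, reps)


def _analysis_step(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Circular correlation with ``filt`` followed by dyadic downsampling:
    ``a_k = sum_m filt[m] * x[(2k + m) mod n]``."""
    L = filt.size
    xe = np.concatenate([x, _wrap(x, L - 1)[: L - 1]])
    return np.convolve(xe, filt[::-1], mode="valid")[::2]


def _upsample_circ_conv(c: np.ndarray, filt: np.ndarray, n: int) -> np.ndarray:
    up = np.zeros(n)
    up[::2] = c
    L = filt.size
    xe = np.concatenate([_wrap(up, L - 1)[-(L - 1):], up])
    return np.convolve(xe, filt, mode="valid")


def _synthesis_step(a: np.ndarray, d: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    n = 2 * a.size
    return _upsample_circ_conv(a, lo, n) + _upsample_circ_conv(d, hi, n)


def wavedec(x: np.ndarray, wavelet: str, levels: int) -> list[np.ndarray]:
    """Multi-level periodized DWT.

    Returns ``[a_L, d_L, d_{L-1}, ..., d_1]`` (coarsest first).  The input
    length must be divisible by ``2**levels``; callers pad beforehand.
    """
    lo, hi = _filters(wavelet)
    x = np.asarray(x, dtype=float)
    if x.size < 2**levels or x.size % 2**levels:
        raise TooShortError(
            f"signal length {x.size} not divisible by 2^{levels}"
        )
    coeffs: list[np.ndarray] = []
    a = x
    for _ in range(levels):
        d = _analysis_step(a, hi)
        a = _analysis_step(a, lo)
        coeffs.append(d)
    coeffs.append(a)
    return coeffs[::-1]


def waverec(coeffs: list[np.ndarray], wavelet: str) -> np.ndarray:
    """Inverse of :func:`wavedec`."""
    lo, hi = _filters(wavelet)
    a = coeffs[0]
    for d in coeffs[1:]:
        a = _synthesis_step(a, d, lo, hi)
    return a


def sure_threshold(d: np.ndarray) -> float:
    """SURE-optimal soft threshold for unit-variance coefficients.

    Minimizes Stein's unbiased risk estimate over thresholds equal to the
    sorted coefficient magnitudes (the classical ``rigrsure`` rule).
    """
    n = d.size
    if n == 0:
        return 0.0
    sq = np.sort(d * d)
    csum = np.cumsum(sq)
    k = np.arange(1, n + 1)
    # risk of thresholding at t = |d|_(k): n - 2k + sum_{i<=k} d_(i)^2 + (n-k) d_(k)^2
    risk = (n - 2.0 * k + csum + (n - k) * sq) / n
    best = int(np.argmin(risk))
    return float(np.sqrt(sq[best]))


def soft(x: np.ndarray, t: float) -> np.ndarray:
    """Soft-thresholding (shrinkage) operator."""
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)
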