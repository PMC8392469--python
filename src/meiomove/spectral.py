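"""Periodograms and short-time spectrograms on a period (minutes) axis.

The periodogram normalisation satisfies Parseval's identity: the summed
power over all nonzero-frequency bins equals the series variance (ddof=0).
"""

from __future__ import annotations

import numpy as np

__all__ = ["periodogram", "dominant_period", "spectrogram"]


def periodogram(series: np.ndarray, dt: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Mean-removed FFT power spectrum mapped to a period axis.

    Returns ``(periods, power)`` for the positive-frequency bins, periods in
    minutes descending toward the Nyquist period 2*dt. Total power equals
    the series variance.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("series too short for a periodogram")
    spec = np.fft.rfft(x - x.mean())
    power = np.abs(spec) ** 2 / n**2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, d=dt)
    periods = np.empty_like(freqs)
    periods[0] = np.inf
    periods[1:] = 1.0 / freqs[1:]
    return periods[1:], power[1:]


def dominant_period(series: np.ndarray, dt: float = 1.0) -> tuple[float, float]:
    """Period (minutes) of the strongest spectral bin and its power share.

    Returns ``(nan, nan)`` for series shorter than 4 frames and
    ``(nan, 0.0)`` for (near-)constant series, which carry no spectral mass.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4:
        return np.nan, np.nan
    periods, power = periodogram(x, dt)
    total = power.sum()
    if total <= 1e-300:
        return np.nan, 0.0
    k = int(np.argmax(power))
    return float(periods[k]), float(power[k] / total)


def spectrogram(
    series: np.ndarray,
    dt: float = 1.0,
    window: float = 30.0,
    hop: int = 1,
    taper: str = "hann",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time tapered periodograms.

    ``window`` is the slice length in minutes; ``hop`` the step between
    slice starts in frames. Returns ``(times, periods, S)`` with S of shape
    (n_periods, n_times); times are slice centres in minutes from the start
    of the series.
    """
    x = np.asarray(series, dtype=float)
    wlen = int(round(window / dt))
    if wlen > x.size:
        raise ValueError(f"window of {wlen} frames longer than series ({x.size})")
    if wlen < 4:
        raise ValueError("window too short")
    if taper == "hann":
        w = np.hanning(wlen)
    elif taper in (None, "boxcar", "none"):
        w = np.ones(wlen)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    starts = np.arange(0, x.size - wlen + 1, hop)
    cols = []
    for s in starts:
        seg = x[s:s + wlen]
        seg = (seg - seg.mean()) * w
        spec = np.abs(np.fft.rfft(seg)) ** 2
        cols.append(spec[1:])
    S = np.array(cols).T
    freqs = np.fft.rfftfreq(wlen, d=dt)[1:]
    periods = 1.0 / freqs
    times = (starts + (wlen - 1) / 2.0) * dt
    return times, periods, S
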