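"""Classical power-spectral EEG features.

All spectral quantities derive from Welch periodograms over non-overlapping
10-s Hamming-tapered windows (0.1-Hz resolution), computed per channel from
its artifact-free windows only.  Band-resolved quantities use the clinical
band scheme in :mod:`icueeg.bands`.  Per-channel values are averaged across
clean channels by the feature assembler to yield one scalar per segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import BANDS, BSI_RANGE, BROADBAND, band_mask
from .montage import homologous_indices
from .preprocess import Segment

__all__ = [
    "SpectrumSet",
    "welch_psd",
    "band_powers",
    "alpha_delta_ratio",
    "sef90",
    "variability",
    "bsi",
    "mean_coherence",
    "shannon_entropy",
    "regularity",
]


@dataclass
class SpectrumSet:
    """Per-channel Welch PSD on a shared frequency grid.

    ``psd`` rows are NaN for channels with no clean window.  ``window_psd``
    keeps the individual 10-s periodograms (channels x windows x freqs) so
    window-resolved statistics (variability) reuse them; ``clean`` is the
    per-(channel, window) validity mask.
    """

    freqs: np.ndarray
    psd: np.ndarray  # channels x freqs, uV^2/Hz
    window_count: np.ndarray  # clean windows per channel
    labels: list[str]
    fs: float
    window_psd: "np.ndarray | None" = None
    clean: "np.ndarray | None" = None

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(segment: Segment) -> SpectrumSet:
    """Welch PSD from non-overlapping 10-s Hamming windows, clean windows only.

    Returns a one-sided density in uV^2/Hz.  Channels whose every window is
    flagged get an all-NaN spectrum (the feature becomes missing downstream).
    """
    w = int(round(segment.window_s * segment.fs))
    n_ch, n_t = segment.samples.shape
    n_win = min(n_t // w, segment.n_windows)
    if n_win < 2:
        raise ValueError("segment must contain at least two 10-s windows")
    x = segment.samples[:, : n_win * w].reshape(n_ch, n_win, w)
    taper = sps.windows.hamming(w, sym=False)  # periodic, Welch convention
    scale = 2.0 / (segment.fs * np.sum(taper**2))
    spec = np.fft.rfft(x * taper, axis=2)
    pxx = (spec.real**2 + spec.imag**2) * scale
    pxx[..., 0] /= 2.0
    if w % 2 == 0:
        pxx[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(w, 1.0 / segment.fs)

    clean = segment.clean_windows[:, :n_win]
    counts = clean.sum(axis=1)
    mean = np.full((n_ch, freqs.size), np.nan)
    for c in range(n_ch):
        if counts[c]:
            mean[c] = pxx[c, clean[c]].mean(axis=0)
    return SpectrumSet(freqs=freqs, psd=mean, window_count=counts,
                       labels=list(segment.labels), fs=segment.fs,
                       window_psd=pxx, clean=clean)


def band_powers(spec: SpectrumSet) -> tuple[np.ndarray, dict, dict]:
    """Total, absolute and relative band power per channel.

    Total power is the PSD summed across all frequency bins (times the bin
    width); absolute band power integrates the PSD over each band; relative
    power is their ratio.  Channels with zero total power yield NaN relative
    power (degenerate spectrum).
    """
    df = spec.df
    total = np.nansum(spec.psd, axis=1) * df
    total[np.isnan(spec.psd).all(axis=1)] = np.nan
    absolute, relative = {}, {}
    for band in BANDS:
        m = band_mask(spec.freqs, band)
        absolute[band] = spec.psd[:, m].sum(axis=1) * df
        with np.errstate(invalid="ignore", divide="ignore"):
            relative[band] = np.where(total > 0, absolute[band] / total, np.nan)
    return total, absolute, relative


def alpha_delta_ratio(abs_power: dict) -> np.ndarray:
    """Normalized alpha-delta contrast (alpha - delta)/(alpha + delta) in [-1, 1]."""
    a, d = np.asarray(abs_power["alpha"], float), np.asarray(abs_power["delta"], float)
    denom = a + d
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (a - d) / denom, np.nan)


def sef90(spec: SpectrumSet, fraction: float = 0.9) -> np.ndarray:
    """Spectral edge frequency: smallest grid frequency below which the given
    fraction of total power lies, per channel."""
    out = np.full(spec.psd.shape[0], np.nan)
    for c, p in enumerate(spec.psd):
        if np.isnan(p).all():
            continue
        cum = np.cumsum(p)
        if cum[-1] <= 0:
            continue
        out[c] = spec.freqs[np.searchsorted(cum, fraction * cum[-1])]
    return out


def variability(spec: SpectrumSet, band: str) -> np.ndarray:
    """Temporal variability of band power: MAD/median over 10-s windows.

    Requires at least 5 clean windows per channel; channels below that yield
    NaN.  A constant power series gives 0.
    """
    if spec.window_psd is None:
        raise ValueError("variability needs window-resolved spectra")
    m = band_mask(spec.freqs, band)
    series = spec.window_psd[:, :, m].sum(axis=2) * spec.df  # ch x windows
    out = np.full(series.shape[0], np.nan)
    for c in range(series.shape[0]):
        vals = series[c, spec.clean[c]]
        if vals.size < 5:
            continue
        med = np.median(vals)
        if med > 0:
            out[c] = np.median(np.abs(vals - med)) / med
    return out


def bsi(spec: SpectrumSet, freq_range: tuple[float, float] = BSI_RANGE) -> float:
    """Pairwise-derived brain symmetry index in [0, 1].

    Mean over homologous left/right electrode pairs and 0.5-20-Hz bins of
    ``|(R - L)/(R + L)|`` where R and L are the per-bin spectral powers; 0
    for perfectly symmetric spectra, 1 when one hemisphere is silent.
    Returns NaN when the montage has no usable homologous pair.
    """
    pairs = homologous_indices(spec.labels)
    m = band_mask(spec.freqs, freq_range)
    vals = []
    for li, ri in pairs:
        left, right = spec.psd[li, m], spec.psd[ri, m]
        if np.isnan(left).all() or np.isnan(right).all():
            continue
        denom = left + right
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.abs(right - left) / denom
        vals.append(np.nanmean(np.where(denom > 0, d, np.nan)))
    return float(np.mean(vals)) if vals else float("nan")


def mean_coherence(segment: Segment, window_s: float = 4.0, overlap_s: float = 2.0,
                   freq_range: tuple[float, float] = BROADBAND) -> float:
    """Mean magnitude-squared coherence over all unordered channel pairs.

    Uses 4-s Hann windows with 2-s overlap; cross-spectra are averaged over
    the frames that are artifact-free on every retained channel, and the MSC
    is averaged over the pass-band frequencies and all pairs.  Identical
    signals on all channels give 1; long independent-noise channels approach
    the small positive MSC estimator floor (~1/#frames).
    """
    n_ch, n_t = segment.samples.shape
    if n_ch < 2:
        return float("nan")
    w = int(round(window_s * segment.fs))
    hop = w - int(round(overlap_s * segment.fs))
    n_frames = (n_t - w) // hop + 1
    taper = sps.windows.hann(w)
    starts = np.arange(n_frames) * hop
    idx = starts[:, None] + np.arange(w)[None, :]
    frames = segment.samples[:, idx] * taper  # ch x frames x w

    # a frame is usable when every 10-s window it touches is clean on all channels
    win_clean = segment.clean_windows.all(axis=0)
    wlen = int(round(segment.window_s * segment.fs))
    first = starts // wlen
    last = (starts + w - 1) // wlen
    ok = np.array([win_clean[f:l + 1].all() if l < win_clean.size else False
                   for f, l in zip(first, last)])
    if ok.sum() < 2:
        return float("nan")

    spec = np.fft.rfft(frames[:, ok], axis=2)  # ch x F x bins
    freqs = np.fft.rfftfreq(w, 1.0 / segment.fs)
    m = band_mask(freqs, freq_range)
    spec = spec[:, :, m]
    auto = np.mean(spec.real**2 + spec.imag**2, axis=1)  # ch x bins
    msc_sum, n_pairs = 0.0, 0
    for i in range(n_ch):
        cross = np.mean(spec[i + 1:] * np.conj(spec[i][None]), axis=1)
        denom = auto[i + 1:] * auto[i][None]
        with np.errstate(invalid="ignore", divide="ignore"):
            msc = np.abs(cross) ** 2 / denom
        msc_sum += np.nanmean(msc, axis=1).sum()
        n_pairs += n_ch - 1 - i
    return float(msc_sum / n_pairs)


def shannon_entropy(spec: SpectrumSet) -> np.ndarray:
    """Spectral Shannon entropy in bits, per channel.

    The one-sided PSD is normalized to a probability distribution over
    frequency bins; ``-sum p log2 p`` is 0 when all power sits in one bin
    and ``log2 N`` for a flat spectrum over N bins.
    """
    out = np.full(spec.psd.shape[0], np.nan)
    for c, p in enumerate(spec.psd):
        if np.isnan(p).all():
            continue
        tot = p.sum()
        if tot <= 0:
            continue
        q = p / tot
        q = q[q > 0]
        out[c] = float(-(q * np.log2(q)).sum())
    return out


def regularity(segment: Segment, smooth_s: float = 0.5) -> np.ndarray:
    """Amplitude-continuity statistic in [0, 1], per channel.

    The squared signal is smoothed with a 0.5-s moving average, sorted in
    descending order into q(1..N), and the statistic is
    ``sqrt(3 * sum(i^2 * q_i) / (N^2 * sum(q_i)))``: 1 for a
    constant-amplitude signal, small for isolated bursts in silence, NaN for
    an all-zero channel.
    """
    from scipy.ndimage import uniform_filter1d

    k = max(int(round(smooth_s * segment.fs)), 1)
    out = np.full(segment.samples.shape[0], np.nan)
    n = segment.samples.shape[1]
    i2 = (np.arange(1, n + 1, dtype=float)) ** 2
    smoothed = uniform_filter1d(segment.samples**2, size=k, axis=1, mode="nearest")
    for c in range(segment.samples.shape[0]):
        q = np.sort(smoothed[c])[::-1]
        s = q.sum()
        if s <= 0:
            continue
        out[c] = min(float(np.sqrt(3.0 * np.dot(i2, q) / (n**2 * s))), 1.0)
    return out
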