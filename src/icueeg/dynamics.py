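"""Temporal-dynamics EEG features.

Three families beyond the classical spectrum:

* **Aperiodic (1/f^alpha) fit** — a robust line in log10-log10 space over
  1-40 Hz with iterative masking of oscillatory peaks; the negative slope is
  the aperiodic exponent, the intercept the offset.
* **Long-range temporal correlations** — detrended fluctuation analysis
  (DFA) of either the channel-summed band amplitude envelope or the global
  phase synchrony (Kuramoto order parameter), yielding a Hurst exponent per
  band.  H = 0.5 is a memoryless process; H > 0.5 indicates persistence.
* **Broken detailed balance** — the band-filtered multichannel signal is
  projected on its first two principal components; the plane is discretized
  into a 3x3 equal-occupancy grid and the lag-1 transition statistics give
  the entropy production (asymmetry of the transition-frequency matrix, in
  nats/step) and the net curl of the probability flux.  Both vanish under
  detailed balance (time-reversible dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import signal as sps

from .bands import BANDS, geometric_center
from .preprocess import Segment
from .spectral import SpectrumSet

__all__ = [
    "AperiodicFit",
    "DFAResult",
    "TransitionModel",
    "fit_aperiodic",
    "band_analytic",
    "kuramoto_order",
    "dfa",
    "lrtc_amplitude",
    "lrtc_phase",
    "pc_trajectory",
    "transition_model",
    "entropy_production_rate",
    "flux_curl",
    "band_analytic_signal",
    "band_decomposition",
]


# ---------------------------------------------------------------------------
# aperiodic component
# ---------------------------------------------------------------------------

@dataclass
class AperiodicFit:
    """Power-law fit of the aperiodic PSD component (log10-log10 space)."""

    offset: float  # log10(uV^2/Hz) at 1 Hz
    exponent: float  # alpha (positive for decaying spectra)
    fit_range: tuple[float, float]
    r2: float


def _fit_channel(logf: np.ndarray, logp: np.ndarray, n_iter: int = 3,
                 z_thresh: float = 2.5) -> tuple[float, float, float]:
    keep = np.ones(logf.size, bool)
    slope = intercept = 0.0
    for _ in range(n_iter + 1):
        slope, intercept = np.polyfit(logf[keep], logp[keep], 1)
        resid = logp - (slope * logf + intercept)
        sd = resid[keep].std()
        if sd < 1e-10:  # numerically exact fit
            break
        new = ~(resid > z_thresh * sd)
        if (new == keep).all() or new.sum() < 5:
            break
        keep = new
    fitted = slope * logf[keep] + intercept
    ss_res = float(((logp[keep] - fitted) ** 2).sum())
    ss_tot = float(((logp[keep] - logp[keep].mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2


def fit_aperiodic(spec: SpectrumSet, fit_range: tuple[float, float] = (1.0, 40.0)
                  ) -> AperiodicFit:
    """Fit the 1/f^alpha background of the channel spectra.

    Per channel: ordinary least squares of log10 PSD on log10 frequency over
    ``fit_range``, iteratively re-fit after masking bins more than 2.5
    residual SDs *above* the line (oscillatory peaks only bias upward), at
    most 3 re-fits.  Offset and exponent are averaged over channels.  A
    noiseless power law is recovered exactly on the first pass.
    """
    m = (spec.freqs >= fit_range[0]) & (spec.freqs <= fit_range[1])
    if m.sum() < 20:
        raise ValueError("need at least 20 frequency bins in the fit range")
    offs, exps, r2s = [], [], []
    for p in spec.psd:
        if np.isnan(p).all():
            continue
        pm = p[m]
        good = pm > 0
        if good.sum() < 5:
            continue
        logf = np.log10(spec.freqs[m][good])
        logp = np.log10(pm[good])
        slope, intercept, r2 = _fit_channel(logf, logp)
        offs.append(intercept)
        exps.append(-slope)
        r2s.append(r2)
    if not offs:
        return AperiodicFit(float("nan"), float("nan"), fit_range, float("nan"))
    return AperiodicFit(float(np.mean(offs)), float(np.mean(exps)), fit_range,
                        float(np.mean(r2s)))


# ---------------------------------------------------------------------------
# analytic signal, synchrony
# ---------------------------------------------------------------------------

def band_analytic_signal(samples: np.ndarray, fs: float,
                         band: "str | tuple[float, float]", order: int = 4,
                         rspec: "np.ndarray | None" = None) -> np.ndarray:
    """Analytic signal of the zero-phase band-passed channels.

    The zero-phase Butterworth band-pass (squared magnitude of the digital
    filter, zero phase — the response of a forward-backward application) and
    the Hilbert transform are applied together in the frequency domain: the
    analytic signal is the inverse FFT of the positive-frequency spectrum
    weighted by ``|H|^2``.  ``rspec`` optionally passes a precomputed rFFT
    of ``samples`` so several bands can share it.  Single precision: the
    narrowband decomposition feeds statistical estimators only.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    n = samples.shape[-1]
    if rspec is None:
        rspec = sfft.rfft(samples, axis=-1)
    freqs = sfft.rfftfreq(n, 1.0 / fs)
    sos = sps.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=freqs, fs=fs)
    gain = np.abs(h) ** 2  # two passes: squared magnitude, zero phase
    y = rspec * gain
    full = np.zeros((*samples.shape[:-1], n), dtype=np.complex64)
    full[..., 0] = y[..., 0]
    if n % 2 == 0:
        full[..., 1:n // 2] = 2.0 * y[..., 1:-1]
        full[..., n // 2] = y[..., -1]
    else:
        full[..., 1:(n + 1) // 2] = 2.0 * y[..., 1:]
    return sfft.ifft(full, axis=-1)


def band_decomposition(samples: np.ndarray, fs: float,
                       band: "str | tuple[float, float]", order: int = 4,
                       rspec: "np.ndarray | None" = None
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Band-filtered signal, envelope and phase in one pass.

    Returns (filtered, envelope, phase), each channels x time; see
    :func:`band_analytic_signal` for the construction.
    """
    analytic = band_analytic_signal(samples, fs, band, order, rspec)
    return analytic.real, np.abs(analytic), np.angle(analytic)


def band_analytic(segment: Segment, band: "str | tuple[float, float]",
                  order: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude envelope and instantaneous phase per channel for one band.

    Channels are band-passed with a zero-phase Butterworth of the given
    design order and Hilbert-transformed; the envelope is the magnitude and
    the phase the angle of the analytic signal.
    """
    _, env, phase = band_decomposition(segment.samples, segment.fs, band, order)
    return env, phase


def kuramoto_order(phases: np.ndarray) -> np.ndarray:
    """Global phase synchrony R(t) = |mean_channels exp(i phase)| in [0, 1]."""
    return np.abs(np.exp(1j * phases).mean(axis=0))


# ---------------------------------------------------------------------------
# detrended fluctuation analysis
# ---------------------------------------------------------------------------

@dataclass
class DFAResult:
    """Hurst exponent from the log-log slope of detrended fluctuations."""

    hurst: float
    window_sizes: np.ndarray
    fluctuations: np.ndarray
    fit_r2: float


def dfa(series: np.ndarray, n_min: int = 16, n_max: "int | None" = None,
        n_sizes: int = 15) -> DFAResult:
    """Detrended fluctuation analysis with linear detrending.

    The demeaned series is integrated (cumulative sum), cut into
    non-overlapping windows of ~``n_sizes`` log-spaced lengths between
    ``n_min`` and ``n_max`` (default: a quarter of the series), each window
    is linearly detrended, and F(n) is the RMS residual.  The Hurst exponent
    is the least-squares slope of log F(n) versus log n.
    """
    x = np.asarray(series, float)
    n_max = n_max or x.size // 4
    if x.size < 4 * n_min or n_max < n_min:
        raise ValueError("series too short for the requested window range")
    sizes = np.unique(np.geomspace(n_min, n_max, n_sizes).round().astype(int))
    if sizes.size < 4:
        raise ValueError("fewer than 4 usable window sizes")
    profile = np.cumsum(x - x.mean())
    flucts = np.empty(sizes.size)
    for k, n in enumerate(sizes):
        m = x.size // n
        seg = profile[: m * n].reshape(m, n)
        t = np.arange(n, dtype=float)
        t -= t.mean()
        denom = float((t**2).sum())
        means = seg.mean(axis=1, keepdims=True)
        slopes = (seg @ t)[:, None] / denom
        resid = seg - means - slopes * t
        flucts[k] = np.sqrt((resid**2).mean())
    good = flucts > 0
    if good.sum() < 4:  # (near-)constant input: no resolvable scaling
        return DFAResult(float("nan"), sizes, flucts, float("nan"))
    sizes, flucts = sizes[good], flucts[good]
    logn, logf = np.log(sizes), np.log(flucts)
    slope, intercept = np.polyfit(logn, logf, 1)
    fitted = slope * logn + intercept
    ss_tot = float(((logf - logf.mean()) ** 2).sum())
    r2 = 1.0 - float(((logf - fitted) ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return DFAResult(float(slope), sizes, flucts, r2)


def _band_window_bounds(segment_len: int, fs: float,
                        band: "str | tuple[float, float]") -> tuple[int, int]:
    """Smallest/largest DFA window for band-resolved envelope dynamics.

    The lower bound is one oscillation of the band's geometric-mean
    frequency, floored at twice the band's inverse bandwidth: a signal
    observed through a band of width B cannot carry envelope fluctuations
    faster than ~1/B, so windows below that scale only measure the filter's
    smoothness (which would bias the Hurst estimate upward), not dynamics.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    one_cycle = int(round(fs / geometric_center(band)))
    resolution_floor = int(round(2.0 * fs / (hi - lo)))
    return max(one_cycle, resolution_floor, 4), segment_len // 4


def lrtc_amplitude(segment: Segment, band: "str | tuple[float, float]") -> DFAResult:
    """Hurst exponent of the channel-summed band amplitude envelope."""
    env, _ = band_analytic(segment, band)
    series = env.sum(axis=0)
    n_min, n_max = _band_window_bounds(series.size, segment.fs, band)
    return dfa(series, n_min=n_min, n_max=n_max)


def lrtc_phase(segment: Segment, band: "str | tuple[float, float]") -> DFAResult:
    """Hurst exponent of the Kuramoto order parameter time course."""
    _, phase = band_analytic(segment, band)
    series = kuramoto_order(phase)
    n_min, n_max = _band_window_bounds(series.size, segment.fs, band)
    return dfa(series, n_min=n_min, n_max=n_max)


# ---------------------------------------------------------------------------
# broken detailed balance
# ---------------------------------------------------------------------------

@dataclass
class TransitionModel:
    """Lag-1 transition statistics of the discretized 2-PC state plane."""

    joint_freq: np.ndarray  # n_states x n_states, sums to 1
    entropy_production: float  # nats/step, >= 0
    flux_curl: float  # net circulation over the grid plaquettes
    n_bins: int


def pc_trajectory(segment: "Segment | np.ndarray",
                  band: "str | tuple[float, float] | None" = None,
                  order: int = 4) -> np.ndarray:
    """Standardized projections onto the first two principal components.

    The (optionally band-filtered) channels x time matrix is decomposed by
    PCA over channels; the sign of each component is fixed by requiring a
    positive loading sum, and each projection is z-scored.  Returns an array
    of shape (2, time).  A plain array input is used as-is (pre-filtered).
    """
    if isinstance(segment, np.ndarray):
        x = segment
    elif band is not None:
        x, _, _ = band_decomposition(segment.samples, segment.fs, band, order)
    else:
        x = segment.samples
    x = x - x.mean(axis=1, keepdims=True)
    cov = x @ x.T / x.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    comps = vecs[:, ::-1][:, :2]  # descending eigenvalue order
    for j in range(comps.shape[1]):
        if comps[:, j].sum() < 0:
            comps[:, j] = -comps[:, j]
    proj = comps.T @ x
    sd = proj.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return proj / sd


def _discretize(axis: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(axis, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, axis, side="right")


def transition_model(trajectory: np.ndarray, n_bins: int = 3, lag: int = 1
                     ) -> TransitionModel:
    """Estimate broken-detailed-balance statistics from a 2-D trajectory.

    Each axis is discretized into ``n_bins`` equal-occupancy bins, giving
    ``n_bins**2`` states.  ``joint_freq[i, j]`` is the fraction of time
    steps with state i at t and state j at t+lag.  The entropy production is
    the pair-regularized asymmetry ``0.5 * sum (F_ij - F_ji) ln(F_ij/F_ji)``
    over pairs observed in both directions; it is non-negative and zero iff
    the observed joint frequencies are symmetric.  The flux curl sums the
    net circulation of the probability flux around the elementary plaquettes
    of the grid, with counterclockwise circulation in the (PC1, PC2) plane
    counted positive.
    """
    traj = np.asarray(trajectory, float)
    if traj.ndim != 2 or traj.shape[0] != 2:
        raise ValueError("trajectory must have shape (2, time)")
    t_len = traj.shape[1]
    if t_len < 100 * lag:
        raise ValueError("trajectory too short for transition statistics")
    bx = _discretize(traj[0], n_bins)
    by = _discretize(traj[1], n_bins)
    states = bx * n_bins + by
    n_states = n_bins * n_bins
    pairs = states[:-lag] * n_states + states[lag:]
    counts = np.bincount(pairs, minlength=n_states * n_states).astype(float)
    joint = counts.reshape(n_states, n_states)
    joint /= joint.sum()
    return TransitionModel(joint_freq=joint,
                           entropy_production=entropy_production_rate(joint),
                           flux_curl=flux_curl(joint, n_bins), n_bins=n_bins)


def entropy_production_rate(joint: np.ndarray) -> float:
    """Pair-regularized entropy production of a joint transition-frequency
    matrix: ``0.5 * sum_{i != j} (F_ij - F_ji) ln(F_ij / F_ji)`` over pairs
    observed in both directions (one-sided pairs are skipped).  Always >= 0;
    0 iff the observed matrix is symmetric."""
    joint = np.asarray(joint, float)
    ep = 0.0
    n = joint.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            fij, fji = joint[i, j], joint[j, i]
            if fij > 0 and fji > 0:
                ep += (fij - fji) * np.log(fij / fji)
    return float(ep)


def flux_curl(joint: np.ndarray, n_bins: int) -> float:
    """Net circulation of the probability flux over the elementary plaquettes
    of the discretized state plane (counterclockwise positive)."""
    net = np.asarray(joint, float) - np.asarray(joint, float).T
    curl = 0.0
    for ix in range(n_bins - 1):
        for iy in range(n_bins - 1):
            # plaquette corners, counterclockwise in the (x, y) plane
            a = ix * n_bins + iy
            b = (ix + 1) * n_bins + iy
            c = (ix + 1) * n_bins + (iy + 1)
            d = ix * n_bins + (iy + 1)
            curl += net[a, b] + net[b, c] + net[c, d] + net[d, a]
    return float(curl)
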