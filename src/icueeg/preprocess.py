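"""EEG preprocessing: filtering, re-referencing, artifact masking, segmentation.

The preprocessing chain for one monitoring timepoint is::

    bandpass -> detect_flat_channels -> common_average -> detect_artifacts
             -> extract_segments

Filtering is a zero-phase (forward-backward) 6th-order Butterworth band-pass
of 0.1-40 Hz.  Flat channels (amplitude variance <= 0.1 uV^2) are identified
*before* common-average referencing, excluded from the average, and dropped
from analysis.  Artifact detection then scans the common-average-referenced
signal in non-overlapping 10-s windows, flagging any (channel, window) whose
absolute amplitude reaches 200 uV or whose variance is >= 1400 uV^2 or
<= 1 uV^2.  The 30 minutes centred on the timepoint of interest are split
into three 10-minute segments; flagged windows are excluded from downstream
window-averaged feature computation on a per-channel basis, which retains
more data than whole-window rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .io import Recording

__all__ = [
    "PreprocessConfig",
    "ArtifactMask",
    "Segment",
    "SegmentSet",
    "bandpass",
    "common_average",
    "detect_flat_channels",
    "detect_artifacts",
    "extract_segments",
    "preprocess_recording",
    "mask_to_frame",
]

#: Artifact flag reasons.
AMPLITUDE, HIGH_VARIANCE, LOW_VARIANCE, FLAT = "amplitude", "high_variance", "low_variance", "flat"


@dataclass(frozen=True)
class PreprocessConfig:
    """All preprocessing thresholds in one place (loadable from YAML)."""

    low_hz: float = 0.1
    high_hz: float = 40.0
    filter_order: int = 6
    window_s: float = 10.0
    amp_thresh_uv: float = 200.0
    var_hi_uv2: float = 1400.0
    var_lo_uv2: float = 1.0
    flat_var_uv2: float = 0.1
    segment_s: float = 600.0
    n_segments: int = 3

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PreprocessConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class ArtifactMask:
    """Per-(channel, 10-s window) artifact flags for one recording.

    ``window_flags[ch, w]`` is True when the window is contaminated;
    ``reasons`` holds the triggering rule name ('' when clean).  Flat
    channels have every window flagged with reason ``flat``.
    """

    window_flags: np.ndarray  # bool, channels x windows
    flat_channels: np.ndarray  # bool, channels
    reasons: np.ndarray  # str, channels x windows
    window_s: float

    def __post_init__(self) -> None:
        if self.flat_channels.any():
            # invariant: flat channel => all its windows flagged
            assert self.window_flags[self.flat_channels].all()


@dataclass
class Segment:
    """One clean 10-min block ready for feature extraction."""

    samples: np.ndarray  # channels x time, uV
    labels: list[str]
    fs: float
    clean_windows: np.ndarray  # bool, channels x n_windows (10-s windows)
    window_s: float = 10.0

    @property
    def n_windows(self) -> int:
        return self.clean_windows.shape[1]


@dataclass
class SegmentSet:
    """Three 10-min segments surrounding one monitoring timepoint."""

    segments: list[Segment]
    timepoint_h: float
    labels: list[str]
    available: bool = True

    @classmethod
    def unavailable(cls, timepoint_h: float) -> "SegmentSet":
        return cls(segments=[], timepoint_h=timepoint_h, labels=[], available=False)


def bandpass(rec: Recording, low: float = 0.1, high: float = 40.0,
             order: int = 6) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward application).

    ``order`` is the design order of the underlying low/high-pass
    prototypes; the two-pass application squares the magnitude response and
    cancels the group delay.
    """
    if rec.fs <= 2 * high:
        raise ValueError(f"fs={rec.fs} too low for a {high}-Hz band edge")
    sos = signal.butter(order, (low, high), btype="bandpass", fs=rec.fs, output="sos")
    # settling margin: sosfiltfilt's default padding must fit the recording
    ntaps = 3 * (2 * sos.shape[0] + 1)
    if rec.n_times <= 3 * ntaps:
        raise ValueError("recording too short for stable zero-phase filtering")
    out = rec.copy()
    out.samples = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return out


def common_average(rec: Recording, exclude: "np.ndarray | None" = None) -> Recording:
    """Re-reference to the common average of the retained channels.

    ``exclude`` is a boolean per-channel mask (e.g. flat channels) left out
    of the average; excluded channels are still re-referenced.  After the
    operation the mean across retained channels is zero at every sample.
    """
    out = rec.copy()
    keep = ~exclude if exclude is not None else np.ones(rec.n_channels, bool)
    if keep.sum() == 0:
        raise ValueError("no channels left to form the common average")
    out.samples = rec.samples - rec.samples[keep].mean(axis=0, keepdims=True)
    return out


def detect_flat_channels(rec: Recording, var_thresh: float = 0.1) -> np.ndarray:
    """Boolean mask of flat channels (amplitude variance <= ``var_thresh`` uV^2)."""
    return rec.samples.var(axis=1) <= var_thresh


def detect_artifacts(rec: Recording, config: PreprocessConfig = PreprocessConfig(),
                     flat: "np.ndarray | None" = None) -> ArtifactMask:
    """Flag contaminated (channel, 10-s window) pairs of a CAR-referenced recording.

    A window is flagged when any sample reaches ``amp_thresh_uv`` in absolute
    value, or its variance is >= ``var_hi_uv2`` or <= ``var_lo_uv2``.  When
    several rules fire, the recorded reason follows the precedence
    amplitude > high_variance > low_variance.
    """
    w = int(round(config.window_s * rec.fs))
    if w > rec.n_times:
        raise ValueError("window longer than recording")
    n_win = rec.n_times // w
    x = rec.samples[:, : n_win * w].reshape(rec.n_channels, n_win, w)
    amp = np.abs(x).max(axis=2) >= config.amp_thresh_uv
    var = x.var(axis=2)
    hi = var >= config.var_hi_uv2
    lo = var <= config.var_lo_uv2
    flags = amp | hi | lo
    reasons = np.full((rec.n_channels, n_win), "", dtype=object)
    reasons[lo] = LOW_VARIANCE
    reasons[hi] = HIGH_VARIANCE
    reasons[amp] = AMPLITUDE
    if flat is None:
        flat = np.zeros(rec.n_channels, bool)
    flags[flat] = True
    reasons[flat] = FLAT
    return ArtifactMask(window_flags=flags, flat_channels=np.asarray(flat, bool),
                        reasons=reasons, window_s=config.window_s)


def extract_segments(rec: Recording, timepoint_h: float, mask: ArtifactMask,
                     config: PreprocessConfig = PreprocessConfig()) -> SegmentSet:
    """Cut the 30 minutes around a timepoint into three 10-min segments.

    The window is centred: [timepoint - 15 min, timepoint + 15 min].  Flat
    channels are dropped entirely; if none remain, the segment set is marked
    unavailable and the timepoint's feature vector becomes missing.
    Per-channel artifact flags are carried into each segment so that
    window-averaged features skip contaminated windows.
    """
    seg_len = int(round(config.segment_s * rec.fs))
    total = config.n_segments * seg_len
    if np.isnan(rec.t_after_trauma):
        start = 0  # recording start is taken as the left edge of the window
    else:
        offset_h = (timepoint_h - config.n_segments * config.segment_s / 7200.0
                    ) - rec.t_after_trauma
        start = int(round(offset_h * 3600.0 * rec.fs))
    if start < 0 or start + total > rec.n_times:
        raise ValueError(
            f"recording does not cover 30 min around t={timepoint_h} h")

    keep = ~mask.flat_channels
    if keep.sum() == 0:
        return SegmentSet.unavailable(timepoint_h)
    labels = [lab for lab, k in zip(rec.labels, keep) if k]

    w = int(round(mask.window_s * rec.fs))
    segments = []
    for s in range(config.n_segments):
        sl = slice(start + s * seg_len, start + (s + 1) * seg_len)
        w0, w1 = sl.start // w, sl.stop // w
        clean = ~mask.window_flags[keep, w0:w1]
        segments.append(Segment(samples=rec.samples[keep, sl].copy(),
                                labels=labels, fs=rec.fs, clean_windows=clean,
                                window_s=mask.window_s))
    return SegmentSet(segments=segments, timepoint_h=timepoint_h, labels=labels)


def preprocess_recording(rec: Recording, timepoint_h: "float | None" = None,
                         config: PreprocessConfig = PreprocessConfig()) -> SegmentSet:
    """Run the full chain on one recording and return its segment set."""
    filtered = bandpass(rec, config.low_hz, config.high_hz, config.filter_order)
    flat = detect_flat_channels(filtered, config.flat_var_uv2)
    if flat.all():
        return SegmentSet.unavailable(
            rec.t_after_trauma if timepoint_h is None else timepoint_h)
    car = common_average(filtered, exclude=flat)
    mask = detect_artifacts(car, config, flat=flat)
    if timepoint_h is None:
        # centre of the recording
        timepoint_h = rec.t_after_trauma + rec.duration / 7200.0 if np.isfinite(
            rec.t_after_trauma) else float("nan")
    return extract_segments(car, timepoint_h, mask, config)


def mask_to_frame(mask: ArtifactMask, labels: list[str]) -> pd.DataFrame:
    """Tidy log of flagged windows: channel, window_start_s, reason."""
    ch, win = np.nonzero(mask.window_flags)
    return pd.DataFrame({
        "channel": [labels[c] for c in ch],
        "window_start_s": win * mask.window_s,
        "reason": [mask.reasons[c, w] for c, w in zip(ch, win)],
    })
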