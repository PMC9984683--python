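"""Small helpers shared across test modules."""

from __future__ import annotations

import numpy as np

import icueeg as q


def make_segment(samples: np.ndarray, fs: float = 256.0,
                 labels: "list[str] | None" = None,
                 window_s: float = 10.0) -> q.Segment:
    """Wrap a channels x time array as an all-clean Segment."""
    samples = np.atleast_2d(np.asarray(samples, float))
    if labels is None:
        labels = list(q.STANDARD_1020[: samples.shape[0]])
    n_win = samples.shape[1] // int(round(window_s * fs))
    return q.Segment(samples=samples, labels=labels, fs=fs,
                     clean_windows=np.ones((samples.shape[0], n_win), bool),
                     window_s=window_s)


def segment_from_recording(rec: q.Recording) -> q.Segment:
    return make_segment(rec.samples, fs=rec.fs, labels=list(rec.labels))
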