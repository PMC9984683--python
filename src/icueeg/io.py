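"""Recording container and EDF import/export.

A :class:`Recording` is the in-memory unit every stage consumes: a channels x
time array in microvolts with 10-20 labels, the sampling rate, and the time
after trauma (hours) at which the first sample was acquired.

EDF (European Data Format) is the interchange format for clinical EEG.
Reading goes through :func:`mne.io.read_raw_edf`.  Writing is done by a
minimal EDF writer (16-bit, physical dimension uV, 1-s data records), since
no EDF export backend is bundled with the scientific stack; the round trip
through MNE's reader is exercised in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .montage import STANDARD_1020

__all__ = ["Recording", "write_edf", "read_edf"]


@dataclass
class Recording:
    """Multichannel scalp EEG in microvolts.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in uV.
    labels : list of str
        10-20 electrode names, unique, one per row of ``samples``.
    fs : float
        Sampling rate in Hz.
    t_after_trauma : float
        Hours after trauma of the first sample (NaN if unknown).
    """

    samples: np.ndarray
    labels: list[str] = field(default_factory=lambda: list(STANDARD_1020))
    fs: float = 256.0
    t_after_trauma: float = float("nan")

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_times / self.fs

    def copy(self) -> "Recording":
        return replace(self, samples=self.samples.copy(), labels=list(self.labels))

    def pick(self, labels: "list[str] | tuple[str, ...]") -> "Recording":
        """Sub-recording restricted to ``labels`` (in the given order)."""
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in pos]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        idx = [pos[lab] for lab in labels]
        return replace(self, samples=self.samples[idx].copy(), labels=list(labels))


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw.ljust(width)


def write_edf(rec: Recording, path: "str | Path") -> Path:
    """Write a recording to a 16-bit EDF file.

    Uses 1-second data records (so ``fs`` must be a whole number) and a
    per-channel symmetric physical range covering the data.  The hours after
    trauma are stored in the recording-identification header field.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_rec = int(np.ceil(rec.n_times / spr))
    data = np.zeros((rec.n_channels, n_rec * spr))
    data[:, : rec.n_times] = rec.samples

    # per-channel symmetric physical range; digital range +-32767
    phys_max = np.maximum(np.max(np.abs(data), axis=1), 1.0)
    phys_max = np.ceil(phys_max)

    ns = rec.n_channels
    hdr = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad(f"Startdate 01-JAN-2000 t_after_trauma_h={rec.t_after_trauma}", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (ns + 1)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    sig_hdr = b"".join(
        [
            b"".join(_pad(f"EEG {lab}", 16) for lab in rec.labels),
            b"".join(_pad("", 80) for _ in range(ns)),
            b"".join(_pad("uV", 8) for _ in range(ns)),
            b"".join(_pad(f"{-m:.0f}", 8) for m in phys_max),
            b"".join(_pad(f"{m:.0f}", 8) for m in phys_max),
            b"".join(_pad("-32767", 8) for _ in range(ns)),
            b"".join(_pad("32767", 8) for _ in range(ns)),
            b"".join(_pad("", 80) for _ in range(ns)),
            b"".join(_pad(str(spr), 8) for _ in range(ns)),
            b"".join(_pad("", 32) for _ in range(ns)),
        ]
    )

    scale = 32767.0 / phys_max[:, None]
    digital = np.clip(np.rint(data * scale), -32767, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(sig_hdr)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
    return path


def read_edf(path: "str | Path", labels: "list[str] | None" = None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (uV).

    Parameters
    ----------
    labels : optional whitelist of 10-20 labels to keep, in the given order.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    data = raw.get_data() * 1e6  # MNE returns Volts

    t_after = float("nan")
    meas_info = raw.info.get("subject_info") or {}
    # hours-after-trauma round-trips via the recording-id header field
    with open(path, "rb") as fh:
        fh.seek(88)
        rec_id = fh.read(80).decode("ascii", errors="replace")
    for token in rec_id.split():
        if token.startswith("t_after_trauma_h="):
            try:
                t_after = float(token.split("=", 1)[1])
            except ValueError:
                pass
    del meas_info

    rec = Recording(samples=data, labels=names, fs=float(raw.info["sfreq"]),
                    t_after_trauma=t_after)
    if labels is not None:
        rec = rec.pick(labels)
    return rec
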