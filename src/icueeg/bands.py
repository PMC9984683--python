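"""Frequency band scheme used throughout the feature set.

The alpha and beta bands deliberately overlap (8-13 vs 10-20 Hz); the scheme
is kept exactly as used clinically for this feature family, and the bands do
not tile the full analysis range, so band powers need not sum to total power.
"""

from __future__ import annotations

import numpy as np

#: name -> (low Hz, high Hz)
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (10.0, 20.0),
}

BAND_NAMES: tuple[str, ...] = tuple(BANDS)

#: Range for the brain symmetry index.
BSI_RANGE: tuple[float, float] = (0.5, 20.0)

#: Broadband analysis range (matches the preprocessing passband).
BROADBAND: tuple[float, float] = (0.5, 40.0)


def band_mask(freqs: np.ndarray, band: "tuple[float, float] | str") -> np.ndarray:
    """Boolean mask selecting frequency bins inside ``band`` (edges inclusive)."""
    lo, hi = BANDS[band] if isinstance(band, str) else band
    return (freqs >= lo) & (freqs <= hi)


def geometric_center(band: "tuple[float, float] | str") -> float:
    """Geometric-mean frequency of a band, used as its nominal oscillation rate."""
    lo, hi = BANDS[band] if isinstance(band, str) else band
    return float(np.sqrt(lo * hi))
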