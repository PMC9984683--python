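"""Electrode montage conventions for the 10-20 International System.

The full clinical montage used here has 19 scalp electrodes.  Hemispheric
features (brain symmetry index) need the homologous left/right pairing; the
odd-numbered electrodes sit over the left hemisphere, even-numbered over the
right, and ``z`` (zero) electrodes on the midline.  A reduced 9-electrode ICU
montage is also accepted anywhere a recording is consumed.
"""

from __future__ import annotations

#: Standard 19-channel 10-20 labels, anterior to posterior.
STANDARD_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Reduced montage used when only a limited electrode set can be placed.
LIMITED_1020: tuple[str, ...] = ("Cz", "O1", "O2", "C3", "C4", "T3", "T4", "Fp1", "Fp2")

#: Homologous (left, right) electrode pairs of the 10-20 system.
HOMOLOGOUS_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("F3", "F4"), ("F7", "F8"), ("C3", "C4"),
    ("T3", "T4"), ("P3", "P4"), ("T5", "T6"), ("O1", "O2"),
)

MIDLINE: tuple[str, ...] = ("Fz", "Cz", "Pz")

LEFT: tuple[str, ...] = tuple(l for l, _ in HOMOLOGOUS_PAIRS)
RIGHT: tuple[str, ...] = tuple(r for _, r in HOMOLOGOUS_PAIRS)


def homologous_indices(labels: "list[str] | tuple[str, ...]") -> list[tuple[int, int]]:
    """Indices of the homologous (left, right) pairs present in ``labels``."""
    pos = {lab: i for i, lab in enumerate(labels)}
    return [(pos[l], pos[r]) for l, r in HOMOLOGOUS_PAIRS if l in pos and r in pos]


def right_indices(labels: "list[str] | tuple[str, ...]") -> list[int]:
    """Indices of right-hemisphere electrodes present in ``labels``."""
    return [i for i, lab in enumerate(labels) if lab in RIGHT]
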