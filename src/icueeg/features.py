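"""Assembly of the quantitative EEG feature vector.

Sixteen feature families are computed per 10-min segment; seven of them are
band-resolved (one value per frequency band), the rest are broadband
scalars, giving 9 + 7 x 4 = 37 numeric columns.  Per-channel quantities are
averaged across clean channels so the classifier receives fixed-length
vectors; features that cannot be computed (flat montage, degenerate power)
are encoded as NaN and imputed later from training folds.

The tidy feature table has one row per (patient, timepoint, segment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bands import BAND_NAMES
from .preprocess import PreprocessConfig, Segment, SegmentSet, preprocess_recording
from . import spectral as sp
from . import dynamics as dyn

__all__ = [
    "FEATURE_FAMILIES",
    "BAND_RESOLVED",
    "feature_columns",
    "extract_segment_features",
    "extract_timepoint_features",
    "extract_cohort_features",
]

#: The sixteen feature families.
FEATURE_FAMILIES: tuple[str, ...] = (
    "total_power", "abs_power", "rel_power", "adr", "sef90", "variability",
    "bsi", "coherence", "shannon_entropy", "regularity",
    "aperiodic_offset", "aperiodic_exponent",
    "dfa_amp", "dfa_phase", "entropy_production", "flux_curl",
)

#: Families computed once per frequency band.
BAND_RESOLVED: frozenset[str] = frozenset(
    {"abs_power", "rel_power", "variability", "dfa_amp", "dfa_phase",
     "entropy_production", "flux_curl"}
)


def feature_columns() -> list[str]:
    """Expanded feature column names (band-resolved families get one column
    per band, e.g. ``abs_power.delta``)."""
    cols: list[str] = []
    for fam in FEATURE_FAMILIES:
        if fam in BAND_RESOLVED:
            cols.extend(f"{fam}.{b}" for b in BAND_NAMES)
        else:
            cols.append(fam)
    return cols


def _chan_mean(values: np.ndarray) -> float:
    values = np.asarray(values, float)
    return float(np.nanmean(values)) if np.isfinite(values).any() else float("nan")


def extract_segment_features(segment: Segment,
                             diagnostics: "dict | None" = None
                             ) -> dict[str, float]:
    """Compute all 37 expanded feature values for one clean segment.

    If ``diagnostics`` is a dict, fit-quality metadata is stored in it:
    clean-window counts, aperiodic fit r2, and the DFA log-log fit r2 per
    band (JSON-serializable, for auditing alongside the feature CSV).
    """
    out: dict[str, float] = {}
    spec = sp.welch_psd(segment)
    if diagnostics is not None:
        diagnostics["clean_windows_per_channel"] = spec.window_count.tolist()
    total, absolute, relative = sp.band_powers(spec)
    out["total_power"] = _chan_mean(total)
    for b in BAND_NAMES:
        out[f"abs_power.{b}"] = _chan_mean(absolute[b])
        out[f"rel_power.{b}"] = _chan_mean(relative[b])
        out[f"variability.{b}"] = _chan_mean(sp.variability(spec, b))
    out["adr"] = _chan_mean(sp.alpha_delta_ratio(absolute))
    out["sef90"] = _chan_mean(sp.sef90(spec))
    out["bsi"] = sp.bsi(spec)
    out["coherence"] = sp.mean_coherence(segment)
    out["shannon_entropy"] = _chan_mean(sp.shannon_entropy(spec))
    out["regularity"] = _chan_mean(sp.regularity(segment))
    ap = dyn.fit_aperiodic(spec)
    out["aperiodic_offset"] = ap.offset
    out["aperiodic_exponent"] = ap.exponent
    if diagnostics is not None:
        diagnostics["aperiodic_r2"] = ap.r2
    from scipy import fft as sfft

    rspec = sfft.rfft(segment.samples, axis=-1)  # shared across bands
    for b in BAND_NAMES:
        analytic = dyn.band_analytic_signal(segment.samples, segment.fs, b,
                                            rspec=rspec)
        env = np.abs(analytic)
        n_min, n_max = dyn._band_window_bounds(
            segment.samples.shape[1], segment.fs, b)
        amp_dfa = dyn.dfa(env.sum(axis=0), n_min=n_min, n_max=n_max)
        out[f"dfa_amp.{b}"] = amp_dfa.hurst
        # Kuramoto order parameter from unit phasors analytic/|analytic|
        with np.errstate(invalid="ignore", divide="ignore"):
            r_t = np.abs((analytic / env).mean(axis=0))
        phase_dfa = dyn.dfa(r_t, n_min=n_min, n_max=n_max)
        out[f"dfa_phase.{b}"] = phase_dfa.hurst
        if diagnostics is not None:
            diagnostics[f"dfa_amp_r2.{b}"] = amp_dfa.fit_r2
            diagnostics[f"dfa_phase_r2.{b}"] = phase_dfa.fit_r2
            diagnostics[f"dfa_windows.{b}"] = int(amp_dfa.window_sizes.size)
        tm = dyn.transition_model(dyn.pc_trajectory(analytic.real))
        out[f"entropy_production.{b}"] = tm.entropy_production
        out[f"flux_curl.{b}"] = tm.flux_curl
    return out


def extract_timepoint_features(segset: SegmentSet, patient_id: str = "") -> pd.DataFrame:
    """Feature rows for the three segments of one timepoint.

    An unavailable segment set (all channels flat) yields a single all-NaN
    row so the timepoint stays visible as missing.
    """
    cols = feature_columns()
    rows = []
    if not segset.available:
        rows.append({"patient_id": patient_id, "timepoint_h": segset.timepoint_h,
                     "segment_id": 0, **{c: np.nan for c in cols}})
    else:
        for i, seg in enumerate(segset.segments):
            rows.append({"patient_id": patient_id, "timepoint_h": segset.timepoint_h,
                         "segment_id": i, **extract_segment_features(seg)})
    return pd.DataFrame(rows, columns=["patient_id", "timepoint_h", "segment_id", *cols])


def extract_cohort_features(recordings, config: PreprocessConfig = PreprocessConfig(),
                            ) -> pd.DataFrame:
    """Run preprocessing + feature extraction over (patient, timepoint, Recording)
    triples and concatenate the tidy feature table."""
    frames = []
    for pid, tp, rec in recordings:
        segset = preprocess_recording(rec, timepoint_h=tp, config=config)
        frames.append(extract_timepoint_features(segset, patient_id=pid))
    return pd.concat(frames, ignore_index=True)
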