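"""Shared fixtures: small deterministic segments and session-scoped synthetic
cohorts (built once; the cohort fixtures dominate the suite's runtime)."""

from __future__ import annotations

import numpy as np
import pytest

import icueeg as q
from icueeg.features import extract_cohort_features, feature_columns
from icueeg.predict import aggregate_features, attach_outcome
from tests_helpers import make_segment


@pytest.fixture(scope="session")
def clean_recording() -> q.Recording:
    """One 10-min default-profile recording (19 channels, 256 Hz)."""
    return q.generate_recording(q.EEGProfile(duration=600.0, seed=7))


@pytest.fixture(scope="session")
def clean_segment(clean_recording) -> q.Segment:
    return make_segment(clean_recording.samples, fs=clean_recording.fs,
                        labels=list(clean_recording.labels))


@pytest.fixture(scope="session")
def planted_cohort():
    """60-patient cohort with 2-SD poor-outcome shifts in alpha power,
    asymmetry (BSI) and envelope variability at 72 h; full 3 x 10-min
    segments.  Returns (model table, cohort, feature column names)."""
    spec = q.CohortSpec(
        n_patients=60, p_poor=0.5,
        effect_sizes={"alpha_power": 2.0, "asymmetry": 2.0, "variability": 2.0},
        timepoints=(72.0,), duration=1800.0, seed=11,
    )
    cohort = q.generate_cohort(spec)
    features = extract_cohort_features(cohort.iter_recordings())
    matrix = aggregate_features(features, 72.0)
    covs = list(q.synth.DEFAULT_COVARIATE_MODEL)
    table = attach_outcome(matrix, cohort.table, covariates=covs)
    return table, cohort, feature_columns()


@pytest.fixture(scope="session")
def timepoint_cohort():
    """50-patient cohort with outcome effects only at 72 h (none at 12 h),
    3 x 5-min segments for speed.  Returns (features, cohort, config)."""
    spec = q.CohortSpec(
        n_patients=50, p_poor=0.5,
        effect_sizes={"alpha_power": 2.0, "asymmetry": 2.0, "variability": 2.0},
        timepoints=(12.0, 72.0), effect_timepoints=(72.0,),
        duration=900.0, seed=13,
    )
    cohort = q.generate_cohort(spec)
    config = q.PreprocessConfig(segment_s=300.0)
    features = extract_cohort_features(cohort.iter_recordings(), config=config)
    return features, cohort, config
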