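"""Simulate a small synthetic ICU-EEG cohort and export it to disk.

Builds an 8-patient cohort with outcome-coupled EEG profiles (poor-outcome
patients get lower alpha power, more delta, more interhemispheric asymmetry
and less alpha variability), writes one EDF per patient/timepoint plus a
cohort CSV with the dichotomized outcome and IMPACT admission covariates.
"""

import tempfile
from pathlib import Path

import icueeg as q

spec = q.CohortSpec(
    n_patients=8,
    p_poor=0.5,
    effect_sizes={"alpha_power": 1.5, "asymmetry": 1.5, "variability": 1.5},
    timepoints=(72.0,),
    duration=300.0,  # 5 min per recording keeps the example quick
    seed=42,
)
cohort = q.generate_cohort(spec)

out_dir = Path(tempfile.mkdtemp(prefix="icueeg_cohort_"))
q.export_cohort(cohort, out_dir)

print(f"cohort written to {out_dir}")
print(cohort.table[["patient_id", "outcome", "age", "glucose", "hemoglobin"]]
      .to_string(index=False))
print(f"\n{int(cohort.table.outcome.sum())} of {len(cohort.table)} patients "
      "have a poor outcome (label 1 = dichotomized GOSE 1-3).")
print("EDF files:", sorted(p.name for p in out_dir.glob("*.edf"))[:3], "...")

rec = q.read_edf(next(out_dir.glob("*.edf")))
print(f"\nround trip: {rec.n_channels} channels @ {rec.fs:g} Hz, "
      f"{rec.duration:g} s, starts {rec.t_after_trauma:g} h after trauma")
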