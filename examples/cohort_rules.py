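"""Cohort inclusion rules and rule-based neurological-decline classification.

Shows the per-rule rejection accounting (shock index >= 0.62 or priority-1,
head AIS > 1, no significant torso trauma, survival >= 15 min, waveforms
available) and the ND composite on an assessment timeline, including the
2-hour analgo-sedation suppression window.
"""

import pandas as pd

from tbivitals.cohort import AssessmentTimeline, apply_inclusion, classify_nd

patients = pd.DataFrame(
    [
        dict(patient_id="A", shock_index=0.90, head_ais=3, abdominal_ais=0, thoracic_ais=1,
             survival_minutes=2000, waveform_available=True),
        dict(patient_id="B", shock_index=0.50, head_ais=3, abdominal_ais=0, thoracic_ais=0,
             survival_minutes=2000, waveform_available=True),
        dict(patient_id="C", shock_index=0.80, head_ais=1, abdominal_ais=0, thoracic_ais=0,
             survival_minutes=2000, waveform_available=True),
        dict(patient_id="D", shock_index=0.80, head_ais=4, abdominal_ais=3, thoracic_ais=0,
             survival_minutes=2000, waveform_available=True),
    ]
)
res = apply_inclusion(patients)
print(f"retained: {list(res.retained['patient_id'])}")
print("rejections:", dict(zip(res.rejected["patient_id"], res.rejected["rejection_reasons"])))

decliner = AssessmentTimeline(gcs=[(60, 14), (300, 12)], marshall=[(90, 2), (600, 3)])
sedated = AssessmentTimeline(gcs=[(60, 14), (170, 12)], sedation_times=[80])
print("decliner:", classify_nd(decliner))
print("sedated (GCS drop 90 min after a dose, suppressed):", classify_nd(sedated))
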