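"""Score one patient's weight series with the weight-based consensus criteria.

The baseline assessment compares the weight closest to diagnosis against
the pre-diagnosis maximum; each post-diagnosis measurement is then encoded
as an ordinal severity category (0 none / 1 pre-cachexia / 2 cachexia).
"""

import numpy as np

from cachetraj import (PatientSeries, baseline_percent_change,
                       classify_consensus, encode_sequence)

patient = PatientSeries(
    patient_id="example",
    pre_times=np.array([-150, -60, -14]),
    pre_weights=np.array([81.0, 82.0, 79.5]),
    pre_bmis=np.array([26.5, 26.8, 26.0]),
    post_times=np.array([0, 30, 90, 180, 270]),
    post_weights=np.array([79.0, 77.5, 74.0, 75.5, 77.0]),
    post_bmis=np.array([25.8, 25.3, 24.2, 24.7, 25.2]),
    event_channels={"overall": (400, 1)},
)

a = baseline_percent_change(patient)
a.category = classify_consensus(a.pct_change, a.baseline_bmi)
print(f"reference (pre-diagnosis max): {a.reference_weight:.1f} kg")
print(f"anchor (closest to diagnosis): {a.anchor_weight:.1f} kg")
print(f"baseline change: {a.pct_change:+.1f}%  ->  category {int(a.category)}")

seq = encode_sequence(patient, a.reference_weight)
for t, v in zip(seq.times, seq.values):
    print(f"  day {t:4d}: category {v}")
# A 3.7% baseline loss is pre-cachexia; the post-diagnosis sequence crosses
# into full cachexia (>5% loss from the 82 kg reference) by day 30 and stays
# there because the partial regain never brings the loss back under 5%.
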