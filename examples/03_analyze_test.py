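"""Score one visual-field test against the normative model.

A 63-year-old's left-eye test is simulated with a superimposed superior
focal defect plus a uniform 1.5 dB diffuse depression (as a media opacity
would cause). Total deviation picks up both; pattern deviation removes the
diffuse component and isolates the focal loss.
"""

import numpy as np

from vfnorm import (
    Eye,
    PatternId,
    analyze,
    build_reference_database,
    default_config,
    simulate_cohort,
    simulate_test,
)
from vfnorm.cohort import sample_demographics
from vfnorm.indices import format_report

config = default_config(seed=1)
cohort = simulate_cohort(config)
model = build_reference_database(
    cohort, PatternId.P24_2, rng=np.random.default_rng(2024)
)

rng = np.random.default_rng(77)
patient = sample_demographics(config, rng)[0]
patient.age = 63
test = simulate_test(
    patient, config.truths[PatternId.P24_2], Eye.OS, rng, config=config, g_std=0.0
)

# superimpose pathology: focal superior loss + mild diffuse depression
values = np.array(test.values)
pattern = model.pattern
perm = pattern.mirror_permutation()  # test.values are in OS enumeration
for j, pt in enumerate(pattern.points):
    if pt.y >= 9 and pt.x <= -9 and not pt.is_blind_spot:
        values[perm.index(j)] -= 9.0
test = test.copy_with(values=[float(v - 1.5) for v in values])

result = analyze(test, model, patient.age)
print(format_report(result, model))
# The TD map flags both the diffuse and the focal loss; the PD map keeps only
# the focal superior defect, and PSD is elevated while MD shows the overall
# depression.
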