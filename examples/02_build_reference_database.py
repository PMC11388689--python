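"""Build a 24-2 normative reference database and inspect what it learned.

One randomly selected eye per subject enters the build. The model holds, per
analyzed point, the cross-sectional age regression (the age-corrected median
surface), pooled residual quantiles (the total-deviation significance
limits), and residual variances; plus global limits for MD, PSD and the
foveal threshold.
"""

import numpy as np

from vfnorm import PatternId, build_reference_database, default_config, simulate_cohort
from vfnorm.patterns import eccentricity

cohort = simulate_cohort(default_config(seed=1))
model = build_reference_database(
    cohort, PatternId.P24_2, rng=np.random.default_rng(2024)
)

an = np.array(model.pattern.analyzed_indices)
decline = -model.slope[an]
print(f"n = {model.n_subjects} subjects, pattern {model.pattern_id.value}")
print(f"mean age decline {decline.mean():.3f} dB/yr "
      f"(SD {decline.std(ddof=0):.3f}, max {decline.max():.3f})")
print(f"=> expected loss over 30 years: up to {30 * decline.max():.1f} dB")

ecc = np.array(model.pattern.eccentricities())
j_c, j_e = an[np.argmin(ecc[an])], an[np.argmax(ecc[an])]
print(f"\n5% total-deviation limit: {model.resid_quantiles[5.0][j_c]:+.2f} dB at "
      f"{ecc[j_c]:.1f} deg vs {model.resid_quantiles[5.0][j_e]:+.2f} dB at "
      f"{ecc[j_e]:.1f} deg")
lo, hi = model.resid_quantiles[0.5][an], model.resid_quantiles[99.5][an]
print(f"tail asymmetry (mean |0.5%| vs |99.5%|): {np.mean(-lo):.2f} vs "
      f"{np.mean(hi):.2f} dB  (losses spread wider than gains)")

print("\nglobal limits (5/2/1/0.5%):")
print("  MD lower ", {k: round(v, 2) for k, v in model.md_limits.items()})
print("  PSD upper", {k: round(v, 2) for k, v in model.psd_limits.items()})
print("  foveal   ", {k: round(v, 2) for k, v in model.foveal_limits.items()})
# Limits widen toward the periphery and the lower tail is the longer one:
# both features must be respected when flagging abnormality.
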