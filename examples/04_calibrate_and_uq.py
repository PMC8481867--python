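"""Calibrate one synthetic subject and quantify parameter uncertainty.

Fits (alpha_v, K_p) by proportional-error Levenberg-Marquardt on the 0-50
min window with alpha_u fixed at the literature nominal 3, then reports the
95% confidence intervals and the Monte-Carlo exclusion fraction used by the
validation stage.
"""

import numpy as np

from bvkinetics import CohortConfig, generate_cohort
from bvkinetics.calibration import fit
from bvkinetics.uq import confidence_summary, sample_parameters

rec = generate_cohort(CohortConfig(n_subjects=1, noise_sd=0.10, seed=7))[0]
tp = rec.true_params
res = fit(rec, (0.0, 50.0), fix_alpha_u=3.0, seed=1)
summary = confidence_summary(res)

print(f"subject {rec.subject_id}: true alpha_v={tp.alpha_v:.3f}, K_p={tp.k_p:.3f}")
print(f"fit converged: {res.converged}, RMSNE {100 * res.rmsne:.1f}% over {res.n_points} points\n")
for name in res.free_names:
    lo, hi = summary.intervals[name]
    print(f"{name:8s} estimate {res.estimates[name]:6.3f}   95% CI [{lo:6.3f}, {hi:6.3f}]")

draws = sample_parameters(res, n=10_000, rng=np.random.default_rng(0))
print(
    f"\nMonte-Carlo draws retained: {draws.draws.shape[0]}/10000 "
    f"({100 * draws.exclusion_fraction:.2f}% excluded as implausible: "
    f"{draws.n_excluded_k_p} with K_p <= 0, {draws.n_excluded_alpha_v} unsimulable)"
)
print(
    "the intervals cover the generating values; the excluded sliver is the\n"
    "normal tail of the K_p interval that crosses zero."
)
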