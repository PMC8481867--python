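"""Pre-calibration data quality: singular values vs calibration window.

Rewriting the model in linear-regression form (response: second derivative
of measured BV change; regressors: infusion rate, -hemorrhage rate, -first
derivative) lets the SVD of the design matrix grade how well a candidate
calibration window [0, T_c] constrains each transfer coefficient.
"""

import numpy as np

from bvkinetics import CohortConfig, generate_cohort, svd_profile

rec = generate_cohort(CohortConfig(n_subjects=1, noise_sd=0.10, seed=7))[0]
grid = np.array([30.0, 50.0, 80.0, 120.0, 180.0])
prof = svd_profile(rec, grid)

print(f"subject {rec.subject_id} ({rec.weight_kg:.1f} kg), noise sd 10%\n")
print("T_c (min)   sigma1(axis)        sigma2(axis)        sigma3(axis)")
for i, t_c in enumerate(prof.t_c_grid):
    cells = [
        f"{prof.sigmas[i, k]:8.2f} ({prof.axes[i, k]:6s})" for k in range(3)
    ]
    print(f"{t_c:8.0f}   " + "  ".join(cells))

print(
    "\nsingular values only grow with the window (nested rows), and the\n"
    "loss-ratio axis (zero_v) dominates the gain-ratio axis (zero_u):\n"
    "hemorrhage leads the protocol, so early windows say most about losses.\n"
    "The 50-min window is the shortest that includes both input types while\n"
    "leaving later bleeds for independent validation."
)
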