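"""Binary fluid-responsiveness validation for one subject.

Propagates calibrated-parameter uncertainty through the model over the
validation window and scores agreement between model and measurement on the
binary question "did blood volume rise above normovolemia?" at the end of
therapy (180 min) and at T*, the time when cumulative infusion first equals
cumulative hemorrhage.
"""

import numpy as np

from bvkinetics import CohortConfig, generate_cohort
from bvkinetics.calibration import fit
from bvkinetics.uq import sample_parameters
from bvkinetics.validation import ExperimentalUncertainty, t_star, validate_subject

rec = generate_cohort(CohortConfig(n_subjects=1, noise_sd=0.10, seed=17))[0]
res = fit(rec, (0.0, 50.0), fix_alpha_u=3.0, seed=1)
draws = sample_parameters(res, n=10_000, rng=np.random.default_rng(0))
exp_unc = ExperimentalUncertainty(c_exp=0.2, sigma_floor=0.1 * rec.weight_kg)

report = validate_subject(rec, draws.draws, exp_unc)
ts = t_star(rec.protocol)

print(f"subject {rec.subject_id} ({rec.weight_kg:.1f} kg)")
print(f"measured dV_B at 180 min: {rec.measured_delta_vb[-1]:.0f} mL")
print(f"P_agreement at 180 min: {report.p_agreement_180:.2f}")
if ts is None:
    print("T*: none (infusion never catches up with the hemorrhage volume)")
else:
    print(f"T*: {ts:.0f} min, P_agreement at T*: {report.p_agreement_tstar:.2f}")
print(
    "\nagreement near 1 means model and experiment classify the subject\n"
    "identically (responder/non-responder) even after allowing for both\n"
    "parameter uncertainty and the 20%-proportional measurement band."
)
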