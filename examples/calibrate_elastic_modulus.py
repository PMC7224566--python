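"""Elastic-modulus selection from virtual rheometry (reduced sweep).

For each candidate shear modulus the plate-gap cell is simulated at two
slab volume fractions; the Kelvin-Voigt relaxation times are mapped to
fibrinogen concentration (inverting the fibrin volume-fraction relation),
fitted log-log, extrapolated to 1-6 mg/mL and compared against the
relaxation-time curve implied by the experimental fibrin-gel fits
G' = 10 c^2.6 Pa, G'' = 0.7 c^1.7 Pa.  This example sweeps two candidates
on a coarse grid; the full four-candidate calibration at 96 x 32 is what
scripts/acceptance.py runs.
"""

import warnings

from clotflow.rheometry import run_calibration

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    sel = run_calibration(candidates_pa=(0.44, 0.89), grid_shape=(64, 24),
                          steps_per_cycle=600)

print(sel["table"].to_string(index=False,
                             float_format=lambda v: f"{v:.4g}"))
print()
print(f"selected lambda_e = {sel['selected_lambda_e_pa']} Pa")
print(f"its relaxation-time relation: log10(lambda_s) = "
      f"{sel['slope']:.3f} log10(c) {sel['intercept']:+.3f}")
print("mse_log10 is the squared log-distance to the experimental curve on")
print("1-6 mg/mL; the candidate with the smallest value is selected")
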