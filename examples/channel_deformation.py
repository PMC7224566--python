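"""Thrombus deformation in a 2D channel flow.

A semicircular shell-core thrombus (shell radius 0.8, core radius 0.6)
sits on the lower wall of a 6 x 2 channel with a parabolic inlet (peak
velocity 0.75).  The shell is permeable (kappa_s = 1e-2), the core nearly
impermeable (kappa_c = 1e-4), and the clot is a neo-Hookean solid with
elastic shear modulus 0.5.  The run integrates the coupled phase-field /
flow / elasticity system to t = 0.96 and reports how far each region's
centroid moved downstream: the permeable shell is dragged by the through-
flow while the stiff, nearly sealed core barely moves.
"""

import numpy as np

from clotflow import Grid, MaterialParams, SolverConfig
from clotflow.analysis import thrombus_centroid
from clotflow.scenarios import make_channel
from clotflow.solver import run

mat = MaterialParams(rho1=1.0, rho2=2.0, eta1=0.15, eta2=0.15,
                     lambda_e0=0.5, sigma=1e-3, h=0.1,
                     kappa_s=1e-2, kappa_c=1e-4)
grid = Grid((96, 32), (6.0, 2.0))
scen = make_channel(0.8, 0.6, grid, mat, max_inlet=0.75)

traj = run(scen, SolverConfig(dt=2e-3, t_end=0.96))
assert not traj.aborted, traj.abort_reason

phi0 = scen.initial_state().phi
shell = (thrombus_centroid(traj.final.phi, grid, scen.shell_mask)[0]
         - thrombus_centroid(phi0, grid, scen.shell_mask)[0])
core = (thrombus_centroid(traj.final.phi, grid, scen.core_mask)[0]
        - thrombus_centroid(phi0, grid, scen.core_mask)[0])

print(f"downstream centroid shift at t = {traj.final.time:.2f}:")
print(f"  shell region : {shell:+.4f}")
print(f"  core region  : {core:+.4f}")
print("the loosely packed shell deforms far more than the dense core,")
print("which is shielded by its low permeability and stiffness")
d = traj.diagnostics
print(f"diagnostics: max divergence criterion {d['div_criterion'].max():.2e},"
      f" bulk VF drift {abs(d['vf'].iloc[-1] - d['vf'].iloc[0]):.2e}")
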