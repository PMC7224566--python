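"""Platelet aggregation in an idealized fusiform aneurysm, and the handoff
of the aggregate to the phase-field model.

Passive platelets seeded through the dilated lumen are carried by a
pulsatile quasi-Poiseuille flow.  Contact with one of three thrombogenic
wall patches (proximal neck, distal neck, bottom of the bulge) triggers
them; after the activation delay tau_act they become adhesive
pseudo-platelets (radius grown 60-fold) that stick to the sites and to each
other.  The stationary aggregate is then converted to an Eulerian volume
fraction through Gaussian envelopes and smoothed into an initial phase
field phi0 = 1 - VF for the continuum solver.
"""

import numpy as np

from clotflow import Grid, MaterialParams
from clotflow.platelets import (FCMConfig, fcm_volume_fraction,
                                handoff_to_phasefield, simulate_aggregation,
                                thrombus_VF)
from clotflow.scenarios import make_aneurysm

grid = Grid((48, 16, 16), (6.0, 1.0, 1.0))
_, sites = make_aneurysm(grid, MaterialParams())

cfg = FCMConfig(r_p=0.001, tau_act=0.2, seed=1)
out = simulate_aggregation(sites, cfg, (6.0, 1.0, 1.0), sites[0].lumen[2],
                           n_platelets=300, cycles=4, steps_per_cycle=40,
                           seed=1)
s = out["stats"]
print(f"after 4 cardiac cycles with {s['n'] + s['removed']} platelets:")
print(f"  passive {s['passive']}, triggered {s['triggered']}, "
      f"activated {s['activated']}, left the domain {s['removed']}")
print(f"  stationary (part of the thrombus): {s['stationary']}, of which "
      f"{100 * s['stationary_near_sites']:.0f}% lie within two capture "
      "radii of a deposition site")

ens = out["ensemble"]
keep = ens.frozen
frozen = type(ens)(ens.x[keep], ens.v[keep], ens.radius[keep],
                   ens.state[keep], ens.trigger_time[keep],
                   ens.frozen[keep], ens.ids[keep])
# widen the envelopes so the coarse handoff grid resolves them; the sparse
# desk-scale ensemble then supplies the aggregate's SHAPE, while its
# amplitude is set to the packed-aggregate fraction (the scaled-down
# particle count cannot itself supply physiological packing)
cfg_vf = cfg.with_(envelope_factor=3.2 * max(grid.spacing) / cfg.r_eff)
psi = fcm_volume_fraction(frozen, grid, cfg_vf)
vf_shape = thrombus_VF(psi, c_Fbg=3.0, c_plat=0.0, config=cfg_vf)
vf = 0.6 * vf_shape / vf_shape.max()
phi0 = handoff_to_phasefield(vf, grid, h=0.1)
print(f"handoff field: peak thrombus VF = {vf.max():.2f} (packed-aggregate "
      f"amplitude), phi0 range [{phi0.min():.3f}, {phi0.max():.3f}]")
print("phi0 seeds the phase-field solver for the deformation stage")
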