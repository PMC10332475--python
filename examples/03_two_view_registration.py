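"""Register two turntable views (0 and 180 degrees) of one seedling.

The acquisition rig images each plant twice, half a turn apart; each view
misses the far surface.  FPFH descriptors on high-curvature feature points
seed a SAC-IA coarse alignment, which ICP refines; the recovered rotation is
compared with the turntable's true 180-degree motion.
"""

import numpy as np

import seedlingpheno as sp
from seedlingpheno.registration import RegistrationParams, register

# a sparser plant keeps descriptor computation quick for a demo
spec = sp.PlantSpec(seed=4, spacing=0.002, needles_per_region=(25, 22, 20, 18))
plant, _ = sp.generate_plant(spec)

views = sp.two_view(plant, occlusion_frac=0.4, seed=4)
result = register(views.view0, views.view180, RegistrationParams(seed=0))

err = result.transform.compose(views.transform.inverse())
print(f"view sizes: {len(views.view0)} and {len(views.view180)} points")
print(f"rotation error vs turntable truth: {np.degrees(err.rotation_angle()):.2f} deg")
print(f"post-registration RMS residual: {result.rms * 1000:.2f} mm")
print(f"merged cloud: {len(result.merged)} points; converged: {result.converged}")
# Rotation error under 2 degrees and an RMS near the 1 mm sensor noise mean
# the two half-views fused into one consistent plant model.
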