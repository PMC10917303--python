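"""Build the desk-scale planar running model and apply morphology scaling.

Constructs the bundled 7-segment, 18-muscle sagittal model, prints its
generic anthropometrics, then scales the thighs and shanks longer and
slimmer and shows how mass, stature, BMI and the Hill parameters
respond.  Run: python examples/01_build_and_scale_model.py
"""

import numpy as np

from morphsim import AnalyticGeometry, Morphology, build_desk_model
from morphsim.model import build_scaled_model, compute_anthropometrics

model = build_desk_model()
geo = AnalyticGeometry(model)

generic = Morphology.generic(model)
scaled = build_scaled_model(model, generic, geo.lmt_anatomical)
mass, stature, bmi = compute_anthropometrics(scaled)
print(f"generic model: {mass:.1f} kg, {stature:.2f} m, BMI {bmi:.2f}")
# -> total mass, standing height and body-mass index of the reference model

tall = generic.copy()
tall.p_s["thigh"] = np.array([0.9, 1.15, 0.9])  # slimmer, 15 % longer thighs
tall.p_s["shank"] = np.array([0.9, 1.15, 0.9])
scaled_tall = build_scaled_model(model, tall, geo.lmt_anatomical)
mass2, stature2, bmi2 = compute_anthropometrics(scaled_tall)
print(f"long-legged variant: {mass2:.1f} kg, {stature2:.2f} m, BMI {bmi2:.2f}")
# segment masses follow constant density (product of the three factors),
# so slimmer segments lose mass even as they lengthen

m = model.muscle("vasti_r")
i = [mm.name for mm in model.muscles].index("vasti_r")
print(f"vasti: generic F_max {m.f_max_iso:.0f} N, l_opt {m.l_m_opt*1e3:.0f} mm "
      f"-> scaled F_max {scaled_tall.muscles[i].f_max_iso:.0f} N, "
      f"l_opt {scaled_tall.muscles[i].l_m_opt*1e3:.0f} mm")
# optimal fiber and tendon slack lengths follow the anatomical-pose
# muscle-tendon length ratio; volumes scale 1:1 with whole-body mass,
# and maximal isometric force = PCSA * specific tension
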