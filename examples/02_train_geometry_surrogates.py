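"""Train a neural muscle-geometry surrogate and check its fidelity.

Samples (segment scale factors, pose) -> (muscle-tendon length, moment
arms) from the closed-form desk geometry, fits the soleus network, and
compares it against the analytic ground truth.
Run: python examples/02_train_geometry_surrogates.py
"""

import numpy as np

from morphsim import build_desk_model
from morphsim.surrogate import (
    excursion_consistency,
    generate_geometry_dataset,
    surrogate_eval,
    train_surrogate,
)

model = build_desk_model()
dataset = generate_geometry_dataset(model, n_models=200, seed=0)
print(f"dataset: {dataset.n_samples('soleus_r')} samples for the uniarticular "
      f"soleus, {dataset.n_samples('gastroc_r')} for the biarticular gastrocnemius")

sur = train_surrogate(dataset, "soleus_r", epochs=1000, batch_size=64, seed=0)
print(f"held-out RMSE: length {sur.holdout_rmse[0]*1e3:.2f} mm, "
      f"moment arm {sur.holdout_rmse[1]*1e3:.2f} mm")
# the fidelity target for the trajectory optimizer is < 1 mm on lengths

l, ldot, arms = surrogate_eval(sur, q_spanned=[0.2], qdot_spanned=[1.5],
                               ps_rel=np.ones(6))
print(f"at 0.2 rad dorsiflexion, 1.5 rad/s: l_mt {l*1e3:.1f} mm, "
      f"ldot {ldot*1e3:.1f} mm/s, plantarflexion arm {arms[0]*1e3:.1f} mm")
# velocity comes from the chain rule on the length head: ldot = dl/dq qdot

cons = excursion_consistency(sur, dataset.tables["soleus_r"]["X"])
print(f"tendon-excursion consistency |R_net + dl/dq|: rms {cons['rms']*1e3:.2f} mm")
# the analytic model satisfies R = -dl/dq exactly; the surrogate's two
# heads agree to within the reported statistic
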