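"""Train per-feature HMMs and decode a ray's posterior similarity map.

Each discrete HMM has 4 hidden tissue states (lumen, intima, pathology,
adventitia), starts in the lumen (the axis point), and emits the 10
quantized feature symbols. Forward-backward yields an 18x4 posterior matrix
per ray — the "similarity map" — and the position-wise argmax is the
decoded tissue sequence. The five per-feature maps are fused with
precision-derived weights alpha_k.
"""

import numpy as np
import pandas as pd

from mhmmseg import PhantomConfig, generate_phantom, multiscale_features
from mhmmseg.mhmm import TrainConfig, mhmm_posterior, train_mhmm
from mhmmseg.rays import STATE_NAMES, build_series_table

tables = []
for i, r in enumerate((1.2, 1.8, 2.4)):
    ph = generate_phantom(PhantomConfig(radius_profile_mm=r, wall_mode="stripped",
                                        noise_variance=40.0, seed=50 + i))
    feats = multiscale_features(ph.volume)
    tables.append(build_series_table(ph.volume, ph.axes[0], feats,
                                     labels=ph.labels, wall_thickness_vox=2,
                                     on_bounds_error="skip", phantom_id=i))
table = pd.concat(tables, ignore_index=True)
table.attrs["n_samples"] = 18

model, _ = train_mhmm(table, TrainConfig(max_iter=0, scheme_mode="fitted"))
print("fusion weights alpha_k (normalized training precisions):")
for f, w in model.weights.items():
    print(f"  {f:11s} alpha = {w:.3f}  (precision {model.precisions[f]:.3f})")

test = generate_phantom(PhantomConfig(radius_profile_mm=2.0, wall_mode="stripped",
                                      noise_variance=40.0, seed=99))
feats = multiscale_features(test.volume)
tab = build_series_table(test.volume, test.axes[0], feats,
                         on_bounds_error="skip")
ray = tab[(tab.axis_index == 20) & (tab.angle_deg == 0.0)]
series = {f: ray[f].to_numpy() for f in model.features}
sim = mhmm_posterior(model, series)

print("\nsimilarity map for one test ray (rows: samples; columns: P(state)):")
print("        lumen  intima  pathol  advent   decoded")
for i, row in enumerate(sim.posteriors):
    name = STATE_NAMES[int(np.argmax(row))]
    print("  v%-4d %.3f   %.3f   %.3f   %.3f   %s"
          % (i + 1, row[0], row[1], row[2], row[3], name))

# The posterior mass hands over from lumen to intima to adventitia as the
# ray walks outward; the position where the argmax leaves the vessel states
# is the detected boundary for this ray.
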