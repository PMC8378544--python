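"""Train a small generator and synthesize a virtual enhancement image.

Trains at reduced size (32x32, 200 steps) so the example finishes in about
half a minute; the default configuration (64x64, 1200 steps) is what the
full replication uses.
"""

import numpy as np

from vne.model import GeneratorConfig, infer_vne, train, _robust_norm
from vne.phantom import PhantomSpec, generate_study

study = generate_study(PhantomSpec(n_patients=4, image_size=32, seed=1))
held_out = [s for s in study.slices if s.patient_id == 3]
training = [s for s in study.slices if s.patient_id != 3]

cfg = GeneratorConfig(image_size=32, steps=200, val_interval=50, seed=2)
model = train([s.triplet for s in training], cfg,
              patient_ids=[s.patient_id for s in training])
print(f"trained {cfg.steps} steps; "
      f"perceptual loss {model.history['g_perc'][0]:.3f} -> "
      f"{model.history['g_perc'][-1]:.3f} "
      f"(best validation {model.best_val_loss:.3f})")

s = held_out[0]
vne = infer_vne(model, s.triplet)   # never sees the LGE image
target = _robust_norm(s.triplet.lge.pixels)
mae = np.abs(vne.pixels - target).mean()
print(f"held-out slice: per-pixel |VNE - LGE| = {mae:.3f} "
      f"(unit-scaled intensities; lower is better)")
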