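"""Calibrate the quantification threshold by a kappa sweep.

Thresholding the analytic model at different fractions above background
trades sensitivity against specificity; the threshold maximising Cohen's
kappa against ground truth is the operating point.  Here truth is defined
from the models themselves at 18%, so the sweep must recover 0.18 with
kappa 1 — the self-consistency check of the calibration machinery.
"""

import numpy as np

from ad3ri.modelling import DrusenModel, ModifiedGaussian
from ad3ri.quantify import model_to_mask, threshold_sweep

rng = np.random.default_rng(0)
models, truths = [], []
for i in range(3):
    gaussians = [
        ModifiedGaussian(x0=40 + 15 * i, y0=50, z0=85.0,
                         A=float(rng.uniform(25, 40)), theta=0.0,
                         sigma_x=6.0, s_F=1.0, d=1.0),
        ModifiedGaussian(x0=88, y0=84, z0=85.0,
                         A=float(rng.uniform(25, 40)), theta=0.6,
                         sigma_x=4.5, s_F=1.4, d=1.0),
    ]
    model = DrusenModel(gaussians=gaussians, background=85.0)
    models.append(model)
    truths.append(model_to_mask(model, (128, 128), 0.18))

table, best = threshold_sweep(models, truths)
print(table.loc[table["threshold"].isin([0.10, 0.14, 0.18, 0.22, 0.30])]
      .to_string(index=False))
print(f"\nargmax-kappa threshold: {best:.2f}")
# kappa peaks at exactly the generating threshold (1.0 at 0.18) and decays
# either side: lower thresholds over-mark (sensitivity 1, specificity
# falls), higher thresholds under-mark.
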