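"""Simulate a paired tau/amyloid PET cohort and recover its latent
structure with constrained parallel ICA.

Prints the recovered cross-modal coupled pair and how faithfully the
spatial sources were separated.
"""

import numpy as np

from petpica.pica import PicaConfig, match_and_align, parallel_ica
from petpica.simulate import SimConfig, synthesize_dataset

config = SimConfig(seed=1)          # 140 subjects, 8 components, r = 0.6
tau, abeta, truth = synthesize_dataset(config)
result = parallel_ica(tau, abeta, PicaConfig(seed=1))

r_abs = np.abs(result.loading_correlation)
i, j = np.unravel_index(r_abs.argmax(), r_abs.shape)
print(f"strongest cross-modal loading pair: tau comp {i} / abeta comp {j}, "
      f"|r| = {r_abs[i, j]:.4f} (simulated ground truth 0.6)")

for mod in ("tau", "abeta"):
    _, _, amari, matched = match_and_align(result.sources[mod],
                                           truth.sources[mod])
    print(f"{mod}: mean matched |map correlation| = {matched.mean():.4f}, "
          f"Amari index = {amari:.4f}")
print("(|map correlation| near 1 and Amari near 0 mean the spatial "
      "sources were recovered up to permutation and sign)")
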