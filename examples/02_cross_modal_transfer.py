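"""Cross-modal decoding: does an emotion classifier transfer between
action modalities?

Trains on all execution trials and tests on imitation trials (and, as a
negative control, on observation trials).  In the default synthetic
ground truth execution and imitation share one emotion pattern while
observation carries none, so transfer succeeds only in one direction —
the planted analogue of a shared neural representation.
"""

import numpy as np

from emodecode import DecodingSpec, VoxelMask, decode
from emodecode.simulate import SyntheticConfig, generate_cohort

config = SyntheticConfig(n_subjects=8, seed=7)
cohort = generate_cohort(config)
roi = VoxelMask("planted", config.roi_specs[0].grid(config.grid_dims))

for train, test in [("execution", "imitation"), ("execution", "observation")]:
    spec = DecodingSpec.cross_modal(train, test)
    accs = [decode(ds, roi, spec).mean_accuracy for ds in cohort]
    print(f"train {train:>11} -> test {test:<11} "
          f"group accuracy {np.mean(accs):5.1f}%  (chance = 50%)")
# Transfer to imitation is far above chance (shared pattern); transfer
# to observation hovers at 50% (no pattern planted there).
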