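"""Group significance of ROI decoding via the two-step permutation test.

Step 1 permutes emotion labels within block per subject (100 times) and
reruns the full cross-validated decode; step 2 bootstraps group means
from the per-subject null accuracies (1e5 draws) and ranks the observed
group mean against them (right-tailed).
"""

from emodecode import DecodingSpec, InferenceConfig, VoxelMask, roi_group_analysis
from emodecode.simulate import SyntheticConfig, generate_cohort

config = SyntheticConfig(n_subjects=10, seed=3)
cohort = generate_cohort(config)
roi = VoxelMask("planted", config.roi_specs[0].grid(config.grid_dims))
inference = InferenceConfig(n_perm=100, n_draws=100_000, seed=0)

for modality in ("imitation", "observation"):
    spec = DecodingSpec.within_modality(modality)
    group, _, null = roi_group_analysis(cohort, roi, spec, inference,
                                        stream=modality)
    print(f"within {modality:<11} accuracy {group.observed_mean:5.1f}%  "
          f"p = {group.p:.4g}  significant: {group.significant}")
# Imitation carries the planted pattern -> p at the smoothed minimum
# 1/(n_draws+1); observation carries none -> p is large and the group
# mean sits inside its own permutation null distribution.
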