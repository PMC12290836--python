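import numpy as np
import pandas as pd
import pytest

from emodecode.datasets import SubjectDataset, TrialTable, VoxelMask
from emodecode.simulate import SyntheticConfig, cuboid_roi


def toy_trial_table(n_blocks=2, trials_per_block=2, modality="execution",
                    subject_id="toy") -> TrialTable:
    """Minimal balanced single-modality design (n_blocks x trials_per_block)."""
    assert trials_per_block % 2 == 0
    rows = []
    idx = 0
    for b in range(1, n_blocks + 1):
        for k in range(trials_per_block):
            rows.append({
                "modality": modality,
                "emotion": "fear" if k < trials_per_block // 2 else "anger",
                "block": b,
                "trial_index": idx,
            })
            idx += 1
    return TrialTable(subject_id, pd.DataFrame(rows))


def dataset_from_table(trials: TrialTable, betas: np.ndarray,
                       brain_mask: np.ndarray | None = None) -> SubjectDataset:
    if brain_mask is None:
        brain_mask = np.ones(betas.shape[1:], dtype=bool)
    return SubjectDataset(trials=trials, betas=betas, brain_mask=brain_mask)


@pytest.fixture
def tiny_config() -> SyntheticConfig:
    """Small grid, strong planted signal shared by execution and imitation."""
    return SyntheticConfig(
        grid_dims=(10, 10, 10),
        roi_specs=(cuboid_roi("planted", (3, 3, 3), (3, 3, 3)),),
        effect_amplitude=1.0,
        noise_sd=0.5,
        n_subjects=4,
        seed=11,
    )


@pytest.fixture
def roi_mask(tiny_config) -> VoxelMask:
    roi = tiny_config.roi_specs[0]
    return VoxelMask("planted", roi.grid(tiny_config.grid_dims))
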