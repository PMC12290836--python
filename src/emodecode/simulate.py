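"""Synthetic cohorts with the facial-emotion imitation study design.

The generator emulates the two study designs and emits trial-wise beta
volumes with a planted, fully known ground truth, so that every
downstream stage (decoding, searchlight, group inference, replication)
has a recoverable target:

* design ``study1`` — imitation, observation and execution conditions
  with 5 blocks x 4 trials each (10 fear + 10 anger per condition) plus
  30 control trials; design ``study2`` — imitation and control with 20
  trials each (5 blocks x 4).
* each trial's beta volume is ``s(emotion) * A * w_m(v) + noise`` where
  ``s(fear) = +1, s(anger) = -1``, ``A`` is the effect amplitude,
  ``w_m`` a unit-norm spatial pattern over the ROI voxels and the noise
  i.i.d. Gaussian over voxels and trials.
* per modality the pattern is the cohort's *reference* pattern
  (``shared``), an independent pattern orthogonalized against the
  reference and all other distinct patterns (``distinct``), or absent
  (``null``).  Cross-modal decoding is therefore above chance exactly
  for pairs of ``shared`` modalities — the planted analogue of a common
  neural representation across action modalities.
* subjects perturb the cohort patterns by Gaussian jitter
  (re-normalized), once per subject, so shared modalities stay aligned
  within subject.

All randomness flows through named substreams of a single master seed;
cohorts are bit-reproducible and subjects independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._rng import substream
from .datasets import SubjectDataset, TrialTable
from .errors import ConfigError

__all__ = [
    "ROISpec",
    "SyntheticConfig",
    "cuboid_roi",
    "default_roi",
    "make_design",
    "generate_subject",
    "generate_cohort",
    "generate_motion_covariates",
]

DESIGNS = ("study1", "study2")
_DESIGN_MODALITIES = {
    "study1": ("imitation", "observation", "execution", "control"),
    "study2": ("imitation", "control"),
}
_SHARING = ("shared", "distinct", "null")


@dataclass(frozen=True)
class ROISpec:
    """A named set of voxels (n x 3 integer index array) carrying a pattern."""

    name: str
    voxels: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=int)
        if vox.ndim != 2 or vox.shape[1] != 3 or len(vox) == 0:
            raise ConfigError(f"roi {self.name!r}: voxels must be a nonempty (n, 3) array")
        object.__setattr__(self, "voxels", vox)

    def grid(self, dims: Sequence[int]) -> np.ndarray:
        g = np.zeros(tuple(dims), dtype=bool)
        g[tuple(self.voxels.T)] = True
        return g


def cuboid_roi(name: str, corner: Sequence[int], size: Sequence[int]) -> ROISpec:
    """Axis-aligned cuboid ROI from a corner voxel and edge lengths."""
    cx, cy, cz = corner
    sx, sy, sz = size
    vox = np.array(
        [(x, y, z)
         for x in range(cx, cx + sx)
         for y in range(cy, cy + sy)
         for z in range(cz, cz + sz)]
    )
    return ROISpec(name, vox)


def default_roi(grid_dims: Sequence[int] = (20, 20, 20)) -> ROISpec:
    """Centered 3x3x3 cube (27 voxels) — the default planted region."""
    corner = [d // 2 - 1 for d in grid_dims]
    return cuboid_roi("planted", corner, (3, 3, 3))


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth description of a synthetic cohort.

    Parameters
    ----------
    effect_amplitude : norm of the planted pattern in beta units (the
        pattern is unit-norm over ROI voxels, so per-voxel amplitude is
        ``effect_amplitude / sqrt(n_roi_voxels)``).
    noise_sd : sd of the i.i.d. Gaussian trial noise (beta units).
    pattern_sharing : modality -> shared | distinct | null, relative to
        the cohort reference pattern; modalities absent from the map
        carry no emotion pattern.
    subject_pattern_jitter : sd of the per-subject pattern perturbation
        (added to the unit-norm pattern, then re-normalized).
    noise_smooth_sigma : optional spatial Gaussian sigma (voxels) applied
        to the noise field; default 0 (off), matching unsmoothed betas.
    emotion_coding : ``sign_flip`` (fear = +pattern, anger = -pattern) or
        ``two_pattern`` (independent fear and anger patterns).
    """

    grid_dims: tuple[int, int, int] = (20, 20, 20)
    roi_specs: tuple[ROISpec, ...] = ()
    effect_amplitude: float = 1.0
    noise_sd: float = 0.5
    pattern_sharing: Mapping[str, str] = field(
        default_factory=lambda: {
            "execution": "shared",
            "imitation": "shared",
            "observation": "null",
        }
    )
    subject_pattern_jitter: float = 0.2
    n_subjects: int = 20
    design: str = "study1"
    seed: int = 0
    noise_smooth_sigma: float = 0.0
    emotion_coding: str = "sign_flip"

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ConfigError(f"unknown design {self.design!r}; expected one of {DESIGNS}")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not self.noise_sd > 0:
            raise ConfigError("noise_sd must be > 0")
        if self.effect_amplitude < 0:
            raise ConfigError("effect_amplitude must be >= 0")
        if self.subject_pattern_jitter < 0:
            raise ConfigError("subject_pattern_jitter must be >= 0")
        if self.emotion_coding not in ("sign_flip", "two_pattern"):
            raise ConfigError(f"unknown emotion_coding {self.emotion_coding!r}")
        rois = tuple(self.roi_specs) or (default_roi(self.grid_dims),)
        dims = np.asarray(self.grid_dims, dtype=int)
        for roi in rois:
            if (roi.voxels < 0).any() or (roi.voxels >= dims).any():
                raise ConfigError(f"roi {roi.name!r} has voxels outside the grid")
        design_mods = set(_DESIGN_MODALITIES[self.design])
        for mod, sharing in self.pattern_sharing.items():
            if mod not in design_mods:
                raise ConfigError(
                    f"pattern_sharing references modality {mod!r} absent from "
                    f"design {self.design!r}"
                )
            if sharing not in _SHARING:
                raise ConfigError(f"unknown pattern sharing {sharing!r} for {mod!r}")
        object.__setattr__(self, "roi_specs", rois)
        object.__setattr__(self, "grid_dims", tuple(int(d) for d in self.grid_dims))
        object.__setattr__(self, "pattern_sharing", dict(self.pattern_sharing))

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def _balanced_block(rng: np.random.Generator, n_per_emotion: int) -> list[str]:
    block = ["fear"] * n_per_emotion + ["anger"] * n_per_emotion
    rng.shuffle(block)
    return block


def make_design(design: str, seed: int = 0, subject_id: str = "design") -> TrialTable:
    """Build the trial table of one of the study designs.

    study1: per acquisition block (5 total), 4 imitation + 4 observation
    + 4 execution trials (2 fear / 2 anger each) followed by 6 control
    trials (3 / 3) — 90 trials, 20 per experimental condition and 30
    control.  study2: 5 blocks of 4 imitation + 4 control trials — 40
    trials.  Emotion order is pseudo-randomized within block, balance
    preserved.
    """
    if design not in DESIGNS:
        raise ConfigError(f"unknown design {design!r}; expected one of {DESIGNS}")
    rng = substream(seed, "design")
    if design == "study1":
        block_plan = [("imitation", 2), ("observation", 2), ("execution", 2),
                      ("control", 3)]
    else:
        block_plan = [("imitation", 2), ("control", 2)]
    rows = []
    idx = 0
    for block in range(1, 6):
        for modality, n_per_emotion in block_plan:
            for emotion in _balanced_block(rng, n_per_emotion):
                rows.append(
                    {"modality": modality, "emotion": emotion,
                     "block": block, "trial_index": idx}
                )
                idx += 1
    return TrialTable(subject_id, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ConfigError("degenerate zero pattern")
    return v / n


def _orthogonalize(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    for b in basis:
        v = v - (v @ b) * b
    return _unit(v)


def _cohort_patterns(config: SyntheticConfig) -> dict[str, dict[str, np.ndarray]]:
    """Cohort-level unit-norm patterns per (roi, modality).

    ``shared`` modalities all point at the ROI's reference pattern;
    each ``distinct`` modality gets its own pattern orthogonal to the
    reference and to every other distinct pattern, so any cross-modal
    pair not sharing the reference decodes at chance in expectation.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for ri, roi in enumerate(config.roi_specs):
        n_vox = len(roi.voxels)
        rng = substream(config.seed, "pattern", ri)
        reference = _unit(rng.standard_normal(n_vox))
        basis = [reference]
        per_mod: dict[str, np.ndarray] = {}
        for mod in sorted(config.pattern_sharing):
            sharing = config.pattern_sharing[mod]
            if sharing == "shared":
                per_mod[mod] = reference
            elif sharing == "distinct":
                if len(basis) >= n_vox:
                    raise ConfigError(
                        f"roi {roi.name!r}: too few voxels to orthogonalize "
                        "another distinct pattern"
                    )
                pat = _orthogonalize(rng.standard_normal(n_vox), basis)
                basis.append(pat)
                per_mod[mod] = pat
        out[roi.name] = per_mod
    return out


def _subject_patterns(config: SyntheticConfig, subject_index: int,
                      cohort: dict[str, dict[str, np.ndarray]]
                      ) -> dict[str, dict[str, np.ndarray]]:
    """Apply per-subject jitter.

    Shared modalities receive the *same* jittered reference within a
    subject (cross-modal alignment survives jitter); each distinct
    modality is jittered independently.
    """
    if config.subject_pattern_jitter == 0:
        return cohort
    out: dict[str, dict[str, np.ndarray]] = {}
    for ri, roi in enumerate(config.roi_specs):
        per_mod = cohort[roi.name]
        rng = substream(config.seed, "pattern", ri, "subject", subject_index)
        jittered: dict[int, np.ndarray] = {}
        out_mod: dict[str, np.ndarray] = {}
        for mod in sorted(per_mod):
            base = per_mod[mod]
            key = id(base)
            if key not in jittered:
                jittered[key] = _unit(
                    base + config.subject_pattern_jitter * rng.standard_normal(len(base))
                )
            out_mod[mod] = jittered[key]
        out[roi.name] = out_mod
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_subject(config: SyntheticConfig, subject_index: int) -> SubjectDataset:
    """Generate one subject: planted patterns + i.i.d. Gaussian noise.

    Deterministic given (config.seed, subject_index); different subject
    indices draw independent noise and jitter substreams.
    """
    if subject_index < 0:
        raise ConfigError("subject_index must be >= 0")
    # per-subject pseudorandomized emotion order within block
    trials = make_design(config.design, seed=_subject_design_seed(config, subject_index),
                         subject_id=f"sub-{subject_index:02d}")
    dims = config.grid_dims
    n_trials = len(trials)
    rng = substream(config.seed, "subject", subject_index)
    betas = rng.normal(0.0, config.noise_sd, size=(n_trials, *dims))
    if config.noise_smooth_sigma > 0:
        for t in range(n_trials):
            betas[t] = gaussian_filter(betas[t], config.noise_smooth_sigma)
    patterns = _subject_patterns(config, subject_index, _cohort_patterns(config))
    emotions = trials.table["emotion"].to_numpy()
    modalities = trials.table["modality"].to_numpy()
    for roi in config.roi_specs:
        per_mod = patterns[roi.name]
        coords = tuple(roi.voxels.T)
        for mod, pattern in per_mod.items():
            if config.emotion_coding == "sign_flip":
                pat_fear, pat_anger = pattern, -pattern
            else:
                prng = substream(config.seed, "pattern", roi.name, mod, "anger",
                                 "subject", subject_index)
                pat_fear = pattern
                pat_anger = _orthogonalize(prng.standard_normal(len(pattern)), [pattern])
            rows = np.nonzero(modalities == mod)[0]
            for t in rows:
                pat = pat_fear if emotions[t] == "fear" else pat_anger
                betas[(t,) + coords] += config.effect_amplitude * pat
    brain_mask = np.ones(dims, dtype=bool)
    return SubjectDataset(
        trials=trials,
        betas=betas,
        brain_mask=brain_mask,
        voxel_size=(3.0, 3.0, 3.0),
        affine=np.diag([3.0, 3.0, 3.0, 1.0]),
        space=f"synthetic-{dims[0]}x{dims[1]}x{dims[2]}",
    )


def _subject_design_seed(config: SyntheticConfig, subject_index: int) -> int:
    # distinct but reproducible per-subject emotion orders
    return int(substream(config.seed, "design", subject_index).integers(0, 2**31 - 1))


def generate_cohort(config: SyntheticConfig) -> list[SubjectDataset]:
    """Generate ``config.n_subjects`` independent subjects (disjoint substreams)."""
    if config.n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    return [generate_subject(config, i) for i in range(config.n_subjects)]


MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


def generate_motion_covariates(trials: TrialTable, seed: int = 0) -> pd.DataFrame:
    """Per-trial six-parameter head-motion table, independent of emotion.

    Simulated as a slow random walk (translations in mm, rotations in
    degrees).  Labels never enter the generation, so decoding emotion
    from these columns succeeds only at chance — the planted analogue of
    the control analysis showing emotional content cannot be classified
    from movement parameters alone.
    """
    rng = substream(seed, "motion")
    n = len(trials)
    steps = rng.normal(0.0, 0.05, size=(n, 6))
    walk = np.cumsum(steps, axis=0)
    walk += rng.normal(0.0, 0.02, size=(n, 6))  # measurement jitter
    return pd.DataFrame(walk, columns=list(MOTION_COLUMNS))
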