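"""Domain types and I/O for trial-wise beta-series decoding.

The pipeline consumes, per subject, a stack of trial-wise parameter
estimate ("beta") volumes, a trial metadata table and a binary brain
mask.  This module defines the validated in-memory containers
(:class:`TrialTable`, :class:`SubjectDataset`, :class:`VoxelMask`,
:class:`ClassifierSpec`), mask algebra, and readers/writers for the
standard on-disk formats: NIfTI-1 for volumes and masks (via nibabel)
and BIDS-style tab-separated events tables (via pandas).

Conventions
-----------
* Voxel coordinates are 0-based (x, y, z) index triples; all geometry is
  done in voxel space.  The NIfTI affine is carried only so that written
  outputs stay aligned with their inputs.
* Trial <-> volume correspondence is positional: row ``i`` of the trial
  table describes volume ``i``.  No filename heuristics.
* Out-of-mask voxels are never features and are written as NaN in maps.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DesignError,
    GridMismatchError,
    InvalidDataError,
    MaskError,
)

MODALITIES = ("execution", "observation", "imitation", "control")
#: Modalities that carry the emotion manipulation with block balance enforced.
EXPERIMENTAL_MODALITIES = ("execution", "observation", "imitation")
EMOTIONS = ("fear", "anger")

TRIAL_COLUMNS = ("modality", "emotion", "block", "trial_index")

__all__ = [
    "MODALITIES",
    "EXPERIMENTAL_MODALITIES",
    "EMOTIONS",
    "TrialTable",
    "SubjectDataset",
    "VoxelMask",
    "ClassifierSpec",
    "combine_masks",
    "read_beta_series",
    "write_subject",
    "read_mask",
    "write_mask",
    "write_map",
    "read_map",
    "write_table",
    "read_trial_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialTable:
    """Per-subject trial metadata in acquisition order.

    One row per trial with columns ``modality`` (execution / observation /
    imitation / control), ``emotion`` (fear / anger), ``block`` (1-based
    acquisition block) and ``trial_index`` (0-based position in the
    acquisition, equal to the volume index).
    """

    subject_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise DesignError(f"design mismatch: trial table missing columns {missing}")
        df = df.reset_index(drop=True)
        bad_mod = set(df["modality"]) - set(MODALITIES)
        if bad_mod:
            raise DesignError(f"design mismatch: unknown modalities {sorted(bad_mod)}")
        bad_emo = set(df["emotion"]) - set(EMOTIONS)
        if bad_emo:
            raise DesignError(f"design mismatch: unknown emotions {sorted(bad_emo)}")
        if (df["block"].astype(int) < 1).any():
            raise DesignError("design mismatch: block numbers must be >= 1")
        idx = df["trial_index"].to_numpy()
        if not np.array_equal(np.sort(idx), np.arange(len(df))):
            raise DesignError(
                "design mismatch: trial_index must be unique and contiguous from 0"
            )
        # block-wise fear/anger balance within every experimental modality;
        # the chance level of 50% and the accuracy definition rely on it
        for mod in EXPERIMENTAL_MODALITIES:
            sub = df[df["modality"] == mod]
            for blk, grp in sub.groupby("block"):
                n_fear = int((grp["emotion"] == "fear").sum())
                n_anger = int((grp["emotion"] == "anger").sum())
                if n_fear != n_anger:
                    raise DesignError(
                        f"design mismatch: modality {mod!r} block {blk} has "
                        f"{n_fear} fear vs {n_anger} anger trials"
                    )
        object.__setattr__(self, "table", df)

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        return self.subject_id == other.subject_id and self.table[
            list(TRIAL_COLUMNS)
        ].equals(other.table[list(TRIAL_COLUMNS)])

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.table["modality"])))

    def with_subject_id(self, subject_id: str) -> "TrialTable":
        return TrialTable(subject_id, self.table.copy())


@dataclass(frozen=True)
class VoxelMask:
    """A named binary voxel mask with a space tag guarding against grid mixing."""

    name: str
    grid: np.ndarray
    space: str = "native"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        if grid.ndim != 3:
            raise GridMismatchError("grid mismatch: mask must be 3-D")
        if not grid.any():
            raise MaskError(f"empty mask: {self.name!r} has no true voxel")
        object.__setattr__(self, "grid", grid)

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def check_compatible(self, shape: Sequence[int], space: str | None = None) -> None:
        if tuple(self.grid.shape) != tuple(shape):
            raise GridMismatchError(
                f"grid mismatch: mask {self.name!r} has dims {self.grid.shape}, "
                f"expected {tuple(shape)}"
            )
        if space is not None and space != self.space:
            raise GridMismatchError(
                f"grid mismatch: mask {self.name!r} is in space {self.space!r}, "
                f"expected {space!r}"
            )


@dataclass(frozen=True)
class ClassifierSpec:
    """Linear max-margin (C-SVC) classifier configuration.

    ``C`` is the box regularization constant (default 1); ``scaling``
    selects optional train-fitted z-scoring of each feature column
    before fitting (applied to train and test alike; default none).
    """

    kind: str = "linear_max_margin"
    C: float = 1.0
    scaling: str = "none"

    def __post_init__(self) -> None:
        if self.kind != "linear_max_margin":
            raise ConfigError(f"unknown classifier kind {self.kind!r}")
        if not self.C > 0:
            raise ConfigError(f"classifier C must be > 0, got {self.C}")
        if self.scaling not in ("none", "zscore_train"):
            raise ConfigError(f"unknown scaling {self.scaling!r}")


@dataclass(frozen=True)
class SubjectDataset:
    """One subject's trial-wise betas, trial table and brain mask.

    ``betas`` has shape (n_trials, nx, ny, nz); ``brain_mask`` shape
    (nx, ny, nz).  All in-mask beta values must be finite for every
    trial.  ``voxel_size`` (mm) and ``affine`` are metadata carried for
    I/O only.
    """

    trials: TrialTable
    betas: np.ndarray
    brain_mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space: str = "native"

    def __post_init__(self) -> None:
        betas = np.asarray(self.betas, dtype=np.float64)
        mask = np.asarray(self.brain_mask, dtype=bool)
        if betas.ndim != 4:
            raise GridMismatchError("grid mismatch: betas must be 4-D (trial, x, y, z)")
        if mask.ndim != 3 or betas.shape[1:] != mask.shape:
            raise GridMismatchError(
                f"grid mismatch: betas spatial dims {betas.shape[1:]} vs "
                f"mask dims {mask.shape}"
            )
        if betas.shape[0] != len(self.trials):
            raise DesignError(
                f"design mismatch: {betas.shape[0]} volumes but "
                f"{len(self.trials)} trial rows"
            )
        if not mask.any():
            raise MaskError("empty mask: brain mask has no true voxel")
        if not np.isfinite(betas[:, mask]).all():
            raise InvalidDataError("invalid betas: non-finite in-mask values")
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "brain_mask", mask)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def subject_id(self) -> str:
        return self.trials.subject_id

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.brain_mask.shape

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    def brain_voxel_mask(self) -> VoxelMask:
        return VoxelMask("brain", self.brain_mask, space=self.space, affine=self.affine)


# ---------------------------------------------------------------------------
# mask algebra
# ---------------------------------------------------------------------------

def combine_masks(masks: Sequence[VoxelMask], name: str) -> VoxelMask:
    """Voxelwise union of masks (e.g. single ROIs into a system mask).

    All masks must share dims and space tag.  Union is commutative,
    associative and idempotent; the result has at least as many voxels
    as the largest input.
    """
    masks = list(masks)
    if not masks:
        raise MaskError("empty mask list: nothing to combine")
    first = masks[0]
    grid = np.zeros(first.shape, dtype=bool)
    for m in masks:
        m.check_compatible(first.shape, first.space)
        grid |= m.grid
    return VoxelMask(name, grid, space=first.space, affine=first.affine)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_trial_table(path: str | os.PathLike, subject_id: str | None = None) -> TrialTable:
    """Read a BIDS-style events TSV (tab-separated, header row) into a TrialTable."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "trial_index" not in df.columns:
        df["trial_index"] = np.arange(len(df))
    sid = subject_id if subject_id is not None else path.stem
    return TrialTable(sid, df)


def _load_betas(path_or_paths) -> tuple[np.ndarray, np.ndarray]:
    """Load one 4-D NIfTI or a list of 3-D NIfTIs; return (betas, affine)."""
    if isinstance(path_or_paths, (str, os.PathLike)):
        img = nib.load(str(path_or_paths))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        if data.ndim == 3:
            data = data[np.newaxis]
        elif data.ndim == 4:
            data = np.moveaxis(data, -1, 0)  # NIfTI stores trial last
        else:
            raise GridMismatchError(
                f"grid mismatch: beta image must be 3-D or 4-D, got {data.ndim}-D"
            )
        return data, np.asarray(img.affine)
    vols = []
    affine = None
    for p in path_or_paths:
        img = nib.load(str(p))
        d = np.asarray(img.get_fdata(), dtype=np.float64)
        if d.ndim != 3:
            raise GridMismatchError("grid mismatch: per-trial beta files must be 3-D")
        if affine is None:
            affine = np.asarray(img.affine)
        vols.append(d)
    if not vols:
        raise InvalidDataError("invalid betas: empty volume list")
    return np.stack(vols, axis=0), affine


def read_beta_series(
    path_or_paths,
    mask_path: str | os.PathLike,
    trials_path: str | os.PathLike,
    subject_id: str | None = None,
    space: str = "native",
) -> SubjectDataset:
    """Assemble a validated SubjectDataset from on-disk NIfTI + TSV.

    ``path_or_paths`` is either one 4-D beta stack or an ordered list of
    3-D per-trial volumes; volume order must equal TSV row order.
    """
    betas, affine = _load_betas(path_or_paths)
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.get_fdata()) > 0.5
    if mask.shape != betas.shape[1:]:
        raise GridMismatchError(
            f"grid mismatch: mask dims {mask.shape} vs beta dims {betas.shape[1:]}"
        )
    trials = read_trial_table(trials_path, subject_id=subject_id)
    if len(trials) != betas.shape[0]:
        raise DesignError(
            f"design mismatch: {betas.shape[0]} volumes but {len(trials)} trial rows"
        )
    zooms = mask_img.header.get_zooms()[:3]
    return SubjectDataset(
        trials=trials,
        betas=betas,
        brain_mask=mask,
        voxel_size=tuple(float(z) for z in zooms),
        affine=affine,
        space=space,
    )


def write_subject(dataset: SubjectDataset, out_dir: str | os.PathLike,
                  stem: str | None = None) -> dict[str, Path]:
    """Write a SubjectDataset as 4-D betas NIfTI + mask NIfTI + events TSV.

    Returns the paths written ({'betas': ..., 'mask': ..., 'events': ...}).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or dataset.subject_id
    paths = {
        "betas": out_dir / f"{stem}_betas.nii.gz",
        "mask": out_dir / f"{stem}_mask.nii.gz",
        "events": out_dir / f"{stem}_events.tsv",
    }
    data = np.moveaxis(dataset.betas, 0, -1)
    nib.save(nib.Nifti1Image(data.astype(np.float64), dataset.affine), str(paths["betas"]))
    nib.save(
        nib.Nifti1Image(dataset.brain_mask.astype(np.uint8), dataset.affine),
        str(paths["mask"]),
    )
    dataset.trials.table.to_csv(paths["events"], sep="\t", index=False)
    return paths


def read_mask(path: str | os.PathLike, name: str | None = None,
              space: str = "native") -> VoxelMask:
    """Read a binary NIfTI mask (any nonzero voxel counts as in-mask)."""
    path = Path(path)
    img = nib.load(str(path))
    grid = np.asarray(img.get_fdata()) > 0.5
    return VoxelMask(name or path.stem, grid, space=space, affine=np.asarray(img.affine))


def write_mask(mask: VoxelMask, path: str | os.PathLike) -> Path:
    affine = mask.affine if mask.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), affine), str(path))
    return Path(path)


def _reference_geometry(reference) -> tuple[tuple[int, int, int], np.ndarray]:
    if isinstance(reference, SubjectDataset):
        return reference.shape, reference.affine
    if isinstance(reference, VoxelMask):
        affine = reference.affine if reference.affine is not None else np.eye(4)
        return reference.shape, affine
    raise TypeError("reference must be a SubjectDataset or VoxelMask")


def write_map(map_grid: np.ndarray, reference, path: str | os.PathLike,
              mask: VoxelMask | np.ndarray | None = None) -> Path:
    """Write a 3-D statistic map as NIfTI with the reference's dims/affine.

    Out-of-mask voxels are written as NaN.  ``mask`` defaults to the
    finite voxels of the map itself.
    """
    shape, affine = _reference_geometry(reference)
    grid = np.asarray(map_grid, dtype=np.float64)
    if grid.shape != tuple(shape):
        raise GridMismatchError(
            f"grid mismatch: map dims {grid.shape} vs reference dims {tuple(shape)}"
        )
    if mask is not None:
        mgrid = mask.grid if isinstance(mask, VoxelMask) else np.asarray(mask, dtype=bool)
        if mgrid.shape != grid.shape:
            raise GridMismatchError("grid mismatch: map vs mask dims")
        if not mgrid.any():
            raise MaskError("empty mask: cannot write an all-masked map")
        out = np.full_like(grid, np.nan)
        out[mgrid] = grid[mgrid]
        grid = out
    nib.save(nib.Nifti1Image(grid, affine), str(path))
    return Path(path)


def read_map(path: str | os.PathLike) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)


RESULT_COLUMNS = ("cohort", "roi", "analysis", "accuracy", "auc", "p", "q",
                  "significant", "n_subjects")


def write_table(rows: Iterable[dict] | pd.DataFrame, path: str | os.PathLike) -> Path:
    """Write a result table as TSV, one row per (cohort x ROI x analysis)."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def dataset_replace(dataset: SubjectDataset, **kwargs) -> SubjectDataset:
    """Functional update of a SubjectDataset (re-runs validation)."""
    return replace(dataset, **kwargs)
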