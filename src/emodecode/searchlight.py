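"""Searchlight information mapping.

A sphere of fixed voxel radius is centered on every voxel of an
analysis mask; the decoding analysis is run on the voxels inside the
sphere (intersected with the brain mask, truncated at grid edges) and
the resulting accuracy is assigned to the center voxel, yielding one
accuracy map per subject per analysis.  Sphere membership uses the
strict inequality ||offset||^2 < radius^2, which gives 93 voxels at the
default radius of 3.

Centers are mutually independent and processed in a fixed lexicographic
order with no shared mutable state, so maps are bit-reproducible under
any execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import SubjectDataset, VoxelMask
from .decoding import (
    DecodingSpec,
    accuracy_from_caches,
    build_split_caches,
    extract_features,  # noqa: F401  (re-exported convenience)
    leave_one_block_out_folds,
    _signed_labels,
)
from .errors import ConfigError, MaskError

__all__ = [
    "SphereIndex",
    "AccuracyMap",
    "sphere_offsets",
    "searchlight_map",
    "searchlight_accuracies",
    "group_mean_map",
]


@dataclass(frozen=True)
class SphereIndex:
    """Integer offsets of the searchlight sphere (includes the origin)."""

    radius: float
    offsets: np.ndarray

    @property
    def n_voxels(self) -> int:
        return len(self.offsets)


def sphere_offsets(radius: float) -> SphereIndex:
    """Enumerate lattice offsets with squared norm strictly below radius^2.

    radius 3 -> 93 offsets; radius 2 -> 27; radius 1 -> just the center.
    The offset list is sorted lexicographically and symmetric under sign
    flips and axis permutations.
    """
    if not radius > 0:
        raise ConfigError(f"sphere radius must be > 0, got {radius}")
    m = int(np.ceil(radius))
    r2 = float(radius) ** 2
    offsets = [
        (x, y, z)
        for x in range(-m, m + 1)
        for y in range(-m, m + 1)
        for z in range(-m, m + 1)
        if x * x + y * y + z * z < r2
    ]
    return SphereIndex(float(radius), np.array(offsets, dtype=np.intp))


@dataclass(frozen=True)
class AccuracyMap:
    """Per-voxel percent accuracies; NaN outside the analysis mask."""

    grid: np.ndarray
    mask: VoxelMask
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.float64)
        if grid.shape != self.mask.shape:
            raise ConfigError("accuracy map and mask dims differ")
        inside = grid[self.mask.grid]
        finite = inside[np.isfinite(inside)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ConfigError("accuracy values must lie in [0, 100]")
        object.__setattr__(self, "grid", grid)


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

def _prepare_trials(dataset: SubjectDataset, spec: DecodingSpec):
    """Resolve trial rows, labels and train/test splits for a spec.

    Returns (rows, labels, splits) where rows index into the dataset's
    trial axis and splits index into ``rows``.
    """
    table = dataset.trials.table
    if spec.cv == "leave_one_block_out":
        sel = spec.train.mask(table)
        if not sel.any():
            raise MaskError("empty selection: no trials match the predicate")
        rows = np.nonzero(sel)[0]
        labels = table.loc[sel, spec.label_column].to_numpy()
        splits = leave_one_block_out_folds(dataset.trials, spec.train)
    else:
        tr_mask = spec.train.mask(table)
        te_mask = spec.test.mask(table)
        if (tr_mask & te_mask).any():
            raise ConfigError("leakage: cv='none' train and test selections share trials")
        if not tr_mask.any() or not te_mask.any():
            raise MaskError("empty selection: no trials match the predicate")
        rows = np.concatenate([np.nonzero(tr_mask)[0], np.nonzero(te_mask)[0]])
        labels = table.loc[rows, spec.label_column].to_numpy()
        n_tr = int(tr_mask.sum())
        splits = [(np.arange(n_tr), np.arange(n_tr, len(rows)))]
    return rows, labels, splits


def searchlight_accuracies(
    dataset: SubjectDataset,
    analysis_mask: VoxelMask,
    spec: DecodingSpec,
    sphere: SphereIndex,
    label_sets: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean accuracy per center for one or many label vectors.

    ``label_sets`` is an optional (n_sets, n_selected_trials) array of
    signed labels; by default the observed labels are used.  Per center
    the sphere's Gram caches are built once and reused across label
    sets, which makes subject-level permutation maps affordable.

    Returns (accuracies with shape (n_sets, n_centers), centers (n, 3),
    sphere sizes per center).
    """
    analysis_mask.check_compatible(dataset.shape)
    rows, labels, splits = _prepare_trials(dataset, spec)
    y_obs, _ = _signed_labels(labels)
    if label_sets is None:
        label_sets = y_obs[np.newaxis, :]
    label_sets = np.asarray(label_sets, dtype=np.float64)
    if label_sets.shape[1] != len(rows):
        raise ConfigError("label_sets length does not match selected trials")

    effective = analysis_mask.grid & dataset.brain_mask
    if not effective.any():
        raise MaskError("empty mask: analysis mask does not intersect the brain mask")
    centers = np.argwhere(effective)
    B = np.ascontiguousarray(dataset.betas[rows])
    brain = dataset.brain_mask
    dims = np.array(dataset.shape)
    offsets = sphere.offsets
    C = spec.classifier.C
    scaling = spec.classifier.scaling

    acc = np.empty((len(label_sets), len(centers)))
    sizes = np.empty(len(centers), dtype=np.intp)
    for ci, center in enumerate(centers):
        coords = center + offsets
        ok = np.all((coords >= 0) & (coords < dims), axis=1)
        coords = coords[ok]
        ok2 = brain[coords[:, 0], coords[:, 1], coords[:, 2]]
        coords = coords[ok2]
        sizes[ci] = len(coords)
        X = B[:, coords[:, 0], coords[:, 1], coords[:, 2]]
        caches = build_split_caches(X, splits, scaling)
        for si in range(len(label_sets)):
            fold_acc, _, _ = accuracy_from_caches(caches, label_sets[si], C)
            acc[si, ci] = fold_acc.mean()
    return acc, centers, sizes


def searchlight_map(
    dataset: SubjectDataset,
    analysis_mask: VoxelMask,
    spec: DecodingSpec,
    sphere: SphereIndex,
) -> AccuracyMap:
    """Whole-mask accuracy map for one subject and one decoding spec."""
    acc, centers, sizes = searchlight_accuracies(dataset, analysis_mask, spec, sphere)
    grid = np.full(dataset.shape, np.nan)
    grid[centers[:, 0], centers[:, 1], centers[:, 2]] = acc[0]
    size_grid = np.zeros(dataset.shape, dtype=int)
    size_grid[centers[:, 0], centers[:, 1], centers[:, 2]] = sizes
    effective_mask = VoxelMask(
        f"{analysis_mask.name}&brain",
        analysis_mask.grid & dataset.brain_mask,
        space=analysis_mask.space,
        affine=analysis_mask.affine if analysis_mask.affine is not None else dataset.affine,
    )
    return AccuracyMap(
        grid=grid,
        mask=effective_mask,
        provenance={
            "subject": dataset.subject_id,
            "radius": sphere.radius,
            "sphere_voxels": sphere.n_voxels,
            "sphere_sizes": size_grid,
            "label_column": spec.label_column,
            "cv": spec.cv,
            "scaling": spec.classifier.scaling,
            "C": spec.classifier.C,
        },
    )


def group_mean_map(maps: list[AccuracyMap]) -> AccuracyMap:
    """Unweighted voxelwise mean across subjects.

    A voxel missing (NaN) in any subject is NaN in the group map, so the
    group mask is the intersection of the subject masks.
    """
    if not maps:
        raise ConfigError("group_mean_map needs at least one map")
    stack = np.stack([m.grid for m in maps])
    mean = stack.mean(axis=0)  # NaN propagates by design
    common = np.isfinite(mean)
    if not common.any():
        raise MaskError("empty mask: no voxel is present in every subject map")
    mask = VoxelMask("group", common, space=maps[0].mask.space,
                     affine=maps[0].mask.affine)
    return AccuracyMap(
        grid=np.where(common, mean, np.nan),
        mask=mask,
        provenance={"n_subjects": len(maps),
                    "subjects": [m.provenance.get("subject") for m in maps]},
    )
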