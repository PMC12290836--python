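"""Group-level significance via the two-step permutation scheme.

Step 1 (subject level): the emotion labels of the training trials are
permuted within block (within modality), the full analysis — fold
structure included — is re-run, and this is repeated ``n_perm`` times
(default 100), yielding a null accuracy distribution per subject.  For
cross-modal analyses only the training labels are permuted; test labels
are untouched.

Step 2 (group level): ``n_draws`` (default 1e5) bootstrap draws each
pick one permutation accuracy per subject at random (with replacement)
and average them, building a null distribution of group mean
accuracies.  The observed group mean is tested right-tailed against it:

    p = (1 + #{draws with mean >= observed}) / (n_draws + 1)

(add-one smoothing keeps p > 0 with finite draws).  The same machinery
applies to ROI scalars and to every searchlight voxel; voxelwise maps
are corrected with Benjamini-Hochberg FDR at alpha = .05.

Replication across sessions or samples is the voxelwise conjunction of
supra-threshold voxels (group mean accuracy >= 60%, and FDR-significant
unless disabled) in the two cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .datasets import SubjectDataset, VoxelMask
from .decoding import (
    DecodingSpec,
    accuracy_from_caches,
    build_split_caches,
    decode,
    extract_features,
    _signed_labels,
)
from .errors import ConfigError, GridMismatchError, MaskError
from .searchlight import (
    AccuracyMap,
    SphereIndex,
    group_mean_map,
    searchlight_accuracies,
)

__all__ = [
    "InferenceConfig",
    "NullDistribution",
    "GroupResult",
    "ReplicationConfig",
    "permutation_label_sets",
    "subject_null",
    "group_bootstrap_p",
    "fdr_correct",
    "roi_group_analysis",
    "searchlight_group_inference",
    "GroupMapResult",
    "replication_overlap",
]


@dataclass(frozen=True)
class InferenceConfig:
    """Two-step permutation test settings (right-tailed throughout)."""

    n_perm: int = 100
    n_draws: int = 100_000
    alpha: float = 0.05
    seed: int = 0
    permutation_unit: str = "within_block"  # or "block_flip"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.n_draws < 1:
            raise ConfigError("n_draws must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.permutation_unit not in ("within_block", "block_flip"):
            raise ConfigError(f"unknown permutation unit {self.permutation_unit!r}")


@dataclass(frozen=True)
class NullDistribution:
    """Subject permutation accuracies and (optionally) bootstrap means."""

    perm_accuracies: np.ndarray  # (n_subjects, n_perm), percent
    bootstrap_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        acc = np.asarray(self.perm_accuracies, dtype=np.float64)
        if acc.ndim != 2:
            raise ConfigError("perm_accuracies must be (subjects, n_perm)")
        if acc.size and (acc.min() < 0 or acc.max() > 100):
            raise ConfigError("accuracies must lie in [0, 100]")
        object.__setattr__(self, "perm_accuracies", acc)


@dataclass(frozen=True)
class GroupResult:
    """Observed group mean with its permutation p (and q for maps)."""

    observed_mean: float
    p: float
    significant: bool
    q: float | None = None
    alpha: float = 0.05
    n_subjects: int = 0
    n_draws: int = 0
    auc: float | None = None


@dataclass(frozen=True)
class ReplicationConfig:
    """Criteria a voxel must meet in *both* cohorts to count as replicated."""

    accuracy_threshold: float = 60.0
    require_significance: bool = True

    def __post_init__(self) -> None:
        if not 50.0 < self.accuracy_threshold <= 100.0:
            raise ConfigError("accuracy_threshold must lie in (50, 100]")


# ---------------------------------------------------------------------------
# subject-level permutations
# ---------------------------------------------------------------------------

def permutation_label_sets(
    trial_rows: pd.DataFrame,
    y_signed: np.ndarray,
    n_train: int,
    n_perm: int,
    rng: np.random.Generator,
    unit: str = "within_block",
) -> np.ndarray:
    """Build (n_perm, n_trials) permuted signed-label vectors.

    Only the first ``n_train`` rows (the training trials; for CV specs
    that is all of them) are permuted, within each (modality, block)
    cell so the design's class balance and the fold structure are
    preserved.  ``block_flip`` instead swaps the labels of whole blocks
    with probability 1/2.
    """
    y_signed = np.asarray(y_signed, dtype=np.float64)
    groups = trial_rows.iloc[:n_train].groupby(["modality", "block"]).indices
    out = np.tile(y_signed, (n_perm, 1))
    for p in range(n_perm):
        for idx in groups.values():
            idx = np.asarray(idx)
            if unit == "within_block":
                out[p, idx] = y_signed[rng.permutation(idx)]
            else:  # block_flip
                if rng.integers(2) == 1:
                    out[p, idx] = -y_signed[idx]
    return out


def _spec_rows_and_labels(dataset: SubjectDataset, spec: DecodingSpec):
    """Selected trial rows (train first), signed labels, splits, n_train."""
    from .searchlight import _prepare_trials

    rows, labels, splits = _prepare_trials(dataset, spec)
    y_signed, classes = _signed_labels(labels)
    if spec.cv == "leave_one_block_out":
        n_train = len(rows)
    else:
        n_train = len(splits[0][0])
    return rows, y_signed, splits, n_train, classes


def subject_null(
    dataset: SubjectDataset,
    mask: VoxelMask,
    spec: DecodingSpec,
    config: InferenceConfig,
    stream: int | str = 0,
) -> np.ndarray:
    """n_perm permutation accuracies for one subject and one analysis.

    The analysis structure (CV folds, train/test split, scaling) is
    retained; only the training labels move.  Deterministic given
    (config.seed, stream).
    """
    rows, y_signed, splits, n_train, _ = _spec_rows_and_labels(dataset, spec)
    sub = dataset.trials.table.iloc[rows].reset_index(drop=True)
    rng = substream(config.seed, "permutation", stream)
    label_sets = permutation_label_sets(
        sub, y_signed, n_train, config.n_perm, rng, config.permutation_unit
    )
    if spec.cv == "leave_one_block_out":
        X, _ = extract_features(dataset, mask, spec.train)
    else:
        X_tr, _ = extract_features(dataset, mask, spec.train)
        X_te, _ = extract_features(dataset, mask, spec.test)
        X = np.vstack([X_tr, X_te])
    caches = build_split_caches(X, splits, spec.classifier.scaling)
    acc = np.empty(config.n_perm)
    for p in range(config.n_perm):
        fold_acc, _, _ = accuracy_from_caches(caches, label_sets[p], spec.classifier.C)
        acc[p] = fold_acc.mean()
    return acc


# ---------------------------------------------------------------------------
# group-level bootstrap
# ---------------------------------------------------------------------------

def _bootstrap_counts(
    observed: np.ndarray,
    perm: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
    chunk: int = 20_000,
) -> np.ndarray:
    """#{draws with group mean >= observed}, vectorized over voxels.

    ``observed``: (n_vox,); ``perm``: (n_subjects, n_perm, n_vox).
    Draw indices are generated in one deterministic stream and shared
    across voxels, which leaves every voxel's marginal p exact while
    keeping the computation a handful of dense gathers.
    """
    n_subj, n_perm, n_vox = perm.shape
    counts = np.zeros(n_vox, dtype=np.int64)
    done = 0
    while done < n_draws:
        c = min(chunk, n_draws - done)
        idx = rng.integers(0, n_perm, size=(c, n_subj))
        means = np.zeros((c, n_vox))
        for s in range(n_subj):
            means += perm[s][idx[:, s], :]
        means /= n_subj
        counts += (means >= observed[np.newaxis, :]).sum(axis=0)
        done += c
    return counts


def group_bootstrap_p(
    observed_mean: float,
    perm_matrix: np.ndarray,
    config: InferenceConfig,
    stream: int | str = 0,
) -> GroupResult:
    """Second step for a scalar (ROI) analysis.

    ``perm_matrix`` is (n_subjects, n_perm).  Per draw one permutation
    accuracy is chosen uniformly per subject; p is the right-tail
    add-one-smoothed rank of the observed group mean among the draw
    means.
    """
    perm = np.asarray(perm_matrix, dtype=np.float64)
    if perm.ndim != 2 or perm.size == 0:
        raise ConfigError("perm_matrix must be a nonempty (subjects, n_perm) array")
    if not np.isfinite(perm).all():
        raise ConfigError("perm_matrix must be finite")
    rng = substream(config.seed, "bootstrap", stream)
    counts = _bootstrap_counts(
        np.array([float(observed_mean)]), perm[:, :, np.newaxis], config.n_draws, rng
    )
    p = float((1 + counts[0]) / (config.n_draws + 1))
    return GroupResult(
        observed_mean=float(observed_mean),
        p=p,
        significant=bool(p <= config.alpha),
        alpha=config.alpha,
        n_subjects=perm.shape[0],
        n_draws=config.n_draws,
    )


def fdr_correct(p_values: np.ndarray, alpha: float = 0.05):
    """Benjamini-Hochberg step-up over a family of p values.

    Returns (q values, significance booleans); q is the monotone
    adjusted p.  NaN entries are excluded from the family and stay NaN.
    """
    p = np.asarray(p_values, dtype=np.float64)
    flat = p.ravel()
    family = np.isfinite(flat)
    if not family.any():
        raise ConfigError("empty family: no finite p values to correct")
    q = np.full(flat.shape, np.nan)
    sig = np.zeros(flat.shape, dtype=bool)
    rej, q_fam, _, _ = multipletests(flat[family], alpha=alpha, method="fdr_bh")
    q[family] = q_fam
    sig[family] = rej
    return q.reshape(p.shape), sig.reshape(p.shape)


# ---------------------------------------------------------------------------
# ROI- and map-level drivers
# ---------------------------------------------------------------------------

def roi_group_analysis(
    datasets: Sequence[SubjectDataset],
    mask: VoxelMask,
    spec: DecodingSpec,
    config: InferenceConfig,
    stream: int | str = 0,
) -> tuple[GroupResult, list, NullDistribution]:
    """Full two-step test of one ROI analysis over a cohort.

    Returns (group result, per-subject DecodingResults, null
    distribution).  ROI p values are used uncorrected at alpha (no
    multiplicity correction across the two ROI systems).
    """
    if not datasets:
        raise ConfigError("empty cohort")
    subject_results = [decode(ds, mask, spec) for ds in datasets]
    perm = np.stack(
        [
            subject_null(ds, mask, spec, config, stream=_sub_stream(stream, i))
            for i, ds in enumerate(datasets)
        ]
    )
    observed = float(np.mean([r.mean_accuracy for r in subject_results]))
    group = group_bootstrap_p(observed, perm, config, stream=stream)
    aucs = [r.auc for r in subject_results if np.isfinite(r.auc)]
    group = GroupResult(
        observed_mean=group.observed_mean,
        p=group.p,
        significant=group.significant,
        alpha=group.alpha,
        n_subjects=group.n_subjects,
        n_draws=group.n_draws,
        auc=float(np.mean(aucs)) if aucs else None,
    )
    return group, subject_results, NullDistribution(perm)


def _sub_stream(stream: int | str, i: int) -> str:
    return f"{stream}/{i}"


@dataclass(frozen=True)
class GroupMapResult:
    """Voxelwise two-step inference over a cohort of searchlight maps."""

    mean_map: AccuracyMap
    p_map: np.ndarray
    q_map: np.ndarray
    significance: np.ndarray  # boolean grid
    alpha: float
    n_subjects: int


def searchlight_group_inference(
    datasets: Sequence[SubjectDataset],
    analysis_mask: VoxelMask,
    spec: DecodingSpec,
    sphere: SphereIndex,
    config: InferenceConfig,
    stream: int | str = 0,
) -> GroupMapResult:
    """Observed group mean map + voxelwise permutation p and BH-FDR q.

    Per subject the observed searchlight map and its ``n_perm``
    permutation maps are computed in one pass (sphere Gram caches are
    shared); the group bootstrap then runs per voxel over the common
    mask.
    """
    if not datasets:
        raise ConfigError("empty cohort")
    subject_maps: list[AccuracyMap] = []
    perm_stacks = []
    centers_ref = None
    for i, ds in enumerate(datasets):
        rows, y_signed, splits, n_train, _ = _spec_rows_and_labels(ds, spec)
        sub = ds.trials.table.iloc[rows].reset_index(drop=True)
        rng = substream(config.seed, "permutation", _sub_stream(stream, i))
        label_sets = permutation_label_sets(
            sub, y_signed, n_train, config.n_perm, rng, config.permutation_unit
        )
        all_sets = np.vstack([y_signed[np.newaxis, :], label_sets])
        acc, centers, sizes = searchlight_accuracies(
            ds, analysis_mask, spec, sphere, label_sets=all_sets
        )
        if centers_ref is None:
            centers_ref = centers
        elif not np.array_equal(centers, centers_ref):
            raise GridMismatchError("grid mismatch: subjects disagree on map voxels")
        grid = np.full(ds.shape, np.nan)
        grid[centers[:, 0], centers[:, 1], centers[:, 2]] = acc[0]
        mask = VoxelMask(f"{analysis_mask.name}&brain",
                         analysis_mask.grid & ds.brain_mask,
                         space=analysis_mask.space, affine=ds.affine)
        subject_maps.append(AccuracyMap(grid, mask,
                                        provenance={"subject": ds.subject_id,
                                                    "radius": sphere.radius}))
        perm_stacks.append(acc[1:])
    mean_map = group_mean_map(subject_maps)
    observed = mean_map.grid[centers_ref[:, 0], centers_ref[:, 1], centers_ref[:, 2]]
    perm = np.stack(perm_stacks)  # (n_subj, n_perm, n_centers)
    rng = substream(config.seed, "bootstrap", stream)
    counts = _bootstrap_counts(observed, perm, config.n_draws, rng)
    p_vec = (1 + counts) / (config.n_draws + 1)
    q_vec, sig_vec = fdr_correct(p_vec, config.alpha)
    shape = mean_map.grid.shape
    p_map = np.full(shape, np.nan)
    q_map = np.full(shape, np.nan)
    sig = np.zeros(shape, dtype=bool)
    cx, cy, cz = centers_ref[:, 0], centers_ref[:, 1], centers_ref[:, 2]
    p_map[cx, cy, cz] = p_vec
    q_map[cx, cy, cz] = q_vec
    sig[cx, cy, cz] = sig_vec
    return GroupMapResult(
        mean_map=mean_map,
        p_map=p_map,
        q_map=q_map,
        significance=sig,
        alpha=config.alpha,
        n_subjects=len(datasets),
    )


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

def replication_overlap(
    map_a: AccuracyMap,
    map_b: AccuracyMap,
    config: ReplicationConfig | None = None,
    sig_a: np.ndarray | None = None,
    sig_b: np.ndarray | None = None,
) -> AccuracyMap:
    """Binary conjunction of supra-threshold voxels in two cohorts.

    A voxel replicates when its group mean accuracy reaches the
    threshold (default 60%) in *both* maps — and, unless
    ``require_significance`` is off, is FDR-significant in both.  The
    output grid holds 1/0 inside the common mask and NaN outside; the
    operation is symmetric in its two inputs.
    """
    config = config or ReplicationConfig()
    if map_a.grid.shape != map_b.grid.shape:
        raise GridMismatchError("grid mismatch: replication maps differ in dims")
    common = np.isfinite(map_a.grid) & np.isfinite(map_b.grid)
    if not common.any():
        raise MaskError("empty mask: maps share no voxels")
    crit = (map_a.grid >= config.accuracy_threshold) & \
           (map_b.grid >= config.accuracy_threshold) & common
    if config.require_significance:
        if sig_a is None or sig_b is None:
            raise ConfigError(
                "require_significance needs significance masks for both cohorts"
            )
        crit &= np.asarray(sig_a, dtype=bool) & np.asarray(sig_b, dtype=bool)
    grid = np.where(common, crit.astype(np.float64), np.nan)
    return AccuracyMap(
        grid=grid,
        mask=VoxelMask("replication", common, space=map_a.mask.space,
                       affine=map_a.mask.affine),
        provenance={
            "accuracy_threshold": config.accuracy_threshold,
            "require_significance": config.require_significance,
            "n_replicated": int(crit.sum()),
        },
    )
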