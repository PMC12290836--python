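"""Experiment orchestration: cohorts -> decodes -> inference -> replication.

`run_experiment` reproduces the full analysis matrix of the study on
one or more cohorts: the three within-modality emotion decodes and the
four directional cross-modal decodes, each evaluated per ROI with the
two-step permutation test, optionally a searchlight with voxelwise
FDR-corrected inference, and replication-overlap maps between cohort
pairs.  All artifacts (result table, NIfTI maps, JSON manifest) land in
the configured output directory; re-running with the same config and
seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import substream
from .datasets import (
    SubjectDataset,
    VoxelMask,
    read_beta_series,
    read_mask,
    write_map,
    write_table,
)
from .decoding import DecodingSpec
from .errors import ConfigError
from .inference import (
    GroupMapResult,
    InferenceConfig,
    ReplicationConfig,
    replication_overlap,
    roi_group_analysis,
    searchlight_group_inference,
)
from .searchlight import AccuracyMap, sphere_offsets
from .simulate import ROISpec, SyntheticConfig, cuboid_roi, generate_cohort

log = logging.getLogger("emodecode")

__all__ = [
    "CohortSpec",
    "SearchlightSettings",
    "ReplicationPlan",
    "ExperimentConfig",
    "ExperimentBundle",
    "table1_analyses",
    "run_experiment",
    "summarize_results",
    "load_experiment_config",
]


def table1_analyses() -> dict[str, DecodingSpec]:
    """The seven-row analysis matrix of the main results table.

    Within-modality emotion decoding for execution, observation and
    imitation (leave-one-block-out CV), and the four directional
    cross-modal decodes; training only ever uses execution or
    observation (imitation is regarded as their compound and is only
    tested on).
    """
    return {
        "within_execution": DecodingSpec.within_modality("execution"),
        "within_observation": DecodingSpec.within_modality("observation"),
        "within_imitation": DecodingSpec.within_modality("imitation"),
        "train_execution_test_imitation": DecodingSpec.cross_modal("execution", "imitation"),
        "train_execution_test_observation": DecodingSpec.cross_modal("execution", "observation"),
        "train_observation_test_imitation": DecodingSpec.cross_modal("observation", "imitation"),
        "train_observation_test_execution": DecodingSpec.cross_modal("observation", "execution"),
    }


@dataclass(frozen=True)
class CohortSpec:
    """One cohort: synthetic config, or per-subject paths on disk.

    ``paths`` entries are dicts {betas, mask, events} per subject.  For
    synthetic cohorts the generator seed is derived from the experiment
    master seed and the cohort name unless ``derive_seed`` is False.
    """

    name: str
    synthetic: SyntheticConfig | None = None
    paths: tuple[Mapping[str, str], ...] | None = None
    derive_seed: bool = True

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.paths is None):
            raise ConfigError(
                f"cohort {self.name!r}: give exactly one of synthetic/paths"
            )


@dataclass(frozen=True)
class SearchlightSettings:
    radius: float = 3.0
    analysis_mask: str = "brain"  # "brain", a ROI name, or a NIfTI path
    analyses: tuple[str, ...] = ("within_execution", "within_imitation",
                                 "train_execution_test_imitation")


@dataclass(frozen=True)
class ReplicationPlan:
    pairs: tuple[tuple[str, str], ...] = ()
    config: ReplicationConfig = field(default_factory=ReplicationConfig)
    analyses: tuple[str, ...] = ("within_execution", "within_imitation",
                                 "train_execution_test_imitation")


@dataclass(frozen=True)
class ExperimentConfig:
    cohorts: tuple[CohortSpec, ...]
    analyses: Mapping[str, DecodingSpec] = field(default_factory=table1_analyses)
    rois: tuple[str, ...] = ("planted",)
    searchlight: SearchlightSettings | None = None
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    replication: ReplicationPlan | None = None
    output_dir: str = "emodecode-results"
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c.name for c in self.cohorts]
        if len(set(names)) != len(names):
            raise ConfigError("cohort names must be unique")
        if len(set(self.analyses)) != len(self.analyses):
            raise ConfigError("analysis names must be unique")
        if self.replication is not None:
            for a, b in self.replication.pairs:
                if a not in names or b not in names:
                    raise ConfigError(
                        f"replication pair ({a!r}, {b!r}) references unknown cohorts"
                    )
            for an in self.replication.analyses:
                if an not in self.analyses:
                    raise ConfigError(f"replication analysis {an!r} not declared")
        if self.searchlight is not None:
            for an in self.searchlight.analyses:
                if an not in self.analyses:
                    raise ConfigError(f"searchlight analysis {an!r} not declared")


@dataclass
class ExperimentBundle:
    """In-memory results + paths of everything written to disk."""

    results: pd.DataFrame
    searchlight: dict[tuple[str, str], GroupMapResult]
    replication: dict[tuple[str, str, str], AccuracyMap]
    manifest: dict
    output_dir: Path


# ---------------------------------------------------------------------------
# cohort and mask resolution
# ---------------------------------------------------------------------------

def _load_cohort(spec: CohortSpec, master_seed: int) -> tuple[list[SubjectDataset], SyntheticConfig | None]:
    if spec.synthetic is not None:
        cfg = spec.synthetic
        if spec.derive_seed:
            derived = int(substream(master_seed, "cohort", spec.name).integers(2**31 - 1))
            cfg = cfg.with_(seed=derived)
        log.info("cohort %s: generating %d synthetic subjects (seed %d)",
                 spec.name, cfg.n_subjects, cfg.seed)
        return generate_cohort(cfg), cfg
    datasets = [
        read_beta_series(p["betas"], p["mask"], p["events"],
                         subject_id=p.get("subject_id"))
        for p in spec.paths
    ]
    log.info("cohort %s: loaded %d subjects from disk", spec.name, len(datasets))
    return datasets, None


def _resolve_roi(roi: str, cohort: list[SubjectDataset],
                 synth: SyntheticConfig | None) -> VoxelMask:
    ds = cohort[0]
    if roi == "brain":
        return ds.brain_voxel_mask()
    if synth is not None:
        for r in synth.roi_specs:
            if r.name == roi:
                return VoxelMask(roi, r.grid(synth.grid_dims), space=ds.space,
                                 affine=ds.affine)
    path = Path(roi)
    if path.exists():
        m = read_mask(path, space=ds.space)
        m.check_compatible(ds.shape)
        return m
    raise ConfigError(f"cannot resolve ROI {roi!r} for this cohort")


def _runnable(spec: DecodingSpec, datasets: list[SubjectDataset]) -> bool:
    """Whether the analysis' modalities exist in this cohort's design."""
    present = set(datasets[0].trials.table["modality"])
    needed = set(spec.train.modalities or ())
    if spec.test is not None:
        needed |= set(spec.test.modalities or ())
    return needed <= present


# ---------------------------------------------------------------------------
# main driver
# ---------------------------------------------------------------------------

def run_experiment(config: ExperimentConfig) -> ExperimentBundle:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inference = InferenceConfig(
        n_perm=config.inference.n_perm,
        n_draws=config.inference.n_draws,
        alpha=config.inference.alpha,
        seed=config.seed,
        permutation_unit=config.inference.permutation_unit,
    )
    rows = []
    sl_results: dict[tuple[str, str], GroupMapResult] = {}
    repl_results: dict[tuple[str, str, str], AccuracyMap] = {}
    cohorts: dict[str, tuple[list[SubjectDataset], SyntheticConfig | None]] = {}

    for cspec in config.cohorts:
        cohorts[cspec.name] = _load_cohort(cspec, config.seed)

    # ROI-level analyses ---------------------------------------------------
    for cname, (datasets, synth) in cohorts.items():
        for roi_name in config.rois:
            mask = _resolve_roi(roi_name, datasets, synth)
            for aname, spec in config.analyses.items():
                if not _runnable(spec, datasets):
                    log.info("cohort %s: skipping %s (modalities absent)", cname, aname)
                    continue
                stream = f"{cname}/{roi_name}/{aname}"
                group, subs, _ = roi_group_analysis(datasets, mask, spec,
                                                    inference, stream=stream)
                log.info("cohort %s roi %s %s: acc %.1f%% p %.4g%s",
                         cname, roi_name, aname, group.observed_mean, group.p,
                         " *" if group.significant else "")
                rows.append({
                    "cohort": cname, "roi": roi_name, "analysis": aname,
                    "accuracy": group.observed_mean,
                    "auc": group.auc if group.auc is not None else np.nan,
                    "p": group.p, "q": np.nan,
                    "significant": group.significant,
                    "n_subjects": group.n_subjects,
                })

    # searchlight ----------------------------------------------------------
    if config.searchlight is not None:
        sphere = sphere_offsets(config.searchlight.radius)
        for cname, (datasets, synth) in cohorts.items():
            amask = _resolve_roi(config.searchlight.analysis_mask, datasets, synth)
            for aname in config.searchlight.analyses:
                spec = config.analyses[aname]
                if not _runnable(spec, datasets):
                    log.info("cohort %s: skipping searchlight %s", cname, aname)
                    continue
                log.info("cohort %s: searchlight %s (radius %.1f, %d centers)",
                         cname, aname, sphere.radius, int(amask.grid.sum()))
                res = searchlight_group_inference(
                    datasets, amask, spec, sphere, inference,
                    stream=f"{cname}/sl/{aname}",
                )
                sl_results[(cname, aname)] = res
                ref = datasets[0]
                stem = out_dir / f"{cname}_{aname}"
                write_map(res.mean_map.grid, ref, f"{stem}_accuracy.nii.gz")
                write_map(res.p_map, ref, f"{stem}_p.nii.gz")
                write_map(res.q_map, ref, f"{stem}_q.nii.gz")
                write_map(res.significance.astype(float), ref, f"{stem}_sig.nii.gz")

    # replication ----------------------------------------------------------
    if config.replication is not None:
        for a, b in config.replication.pairs:
            for aname in config.replication.analyses:
                ra = sl_results.get((a, aname))
                rb = sl_results.get((b, aname))
                if ra is None or rb is None:
                    raise ConfigError(
                        f"replication needs searchlight results for {a!r} and {b!r} "
                        f"on {aname!r}; add them to searchlight.analyses"
                    )
                overlap = replication_overlap(
                    ra.mean_map, rb.mean_map, config.replication.config,
                    sig_a=ra.significance, sig_b=rb.significance,
                )
                repl_results[(a, b, aname)] = overlap
                n_rep = overlap.provenance["n_replicated"]
                log.info("replication %s x %s %s: %d voxels", a, b, aname, n_rep)
                ref = cohorts[a][0][0]
                write_map(overlap.grid, ref,
                          out_dir / f"replication_{a}_{b}_{aname}.nii.gz")

    results = pd.DataFrame(
        rows, columns=["cohort", "roi", "analysis", "accuracy", "auc", "p", "q",
                       "significant", "n_subjects"],
    )
    write_table(results, out_dir / "results.tsv")
    manifest = _manifest(config, results)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ExperimentBundle(results=results, searchlight=sl_results,
                            replication=repl_results, manifest=manifest,
                            output_dir=out_dir)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (ROISpec,)):
        return {"name": obj.name, "voxels": obj.voxels.tolist()}
    return str(obj)


def _manifest(config: ExperimentConfig, results: pd.DataFrame) -> dict:
    cfg_dict = json.loads(json.dumps(asdict_safe(config), default=_json_default))
    table_bytes = results.round(10).to_csv(index=False).encode()
    return {
        "package": "emodecode",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "results_sha256": hashlib.sha256(table_bytes).hexdigest(),
    }


def asdict_safe(config) -> dict:
    d = asdict(config)
    d["analyses"] = {k: asdict(v) for k, v in config.analyses.items()}
    return d


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def summarize_results(bundle: ExperimentBundle) -> str:
    """Human-readable report: accuracy/AUC table + replicated clusters."""
    from scipy import ndimage

    lines = ["# Decoding results", ""]
    if len(bundle.results):
        df = bundle.results.copy()
        df["accuracy"] = df["accuracy"].map(
            lambda v: f"{v:.1f}" if np.isfinite(v) else "-")
        df["auc"] = df["auc"].map(lambda v: f"{v:.3f}" if np.isfinite(v) else "-")
        df["p"] = bundle.results["p"].map(lambda v: f"{v:.4g}")
        df["q"] = bundle.results["q"].map(lambda v: f"{v:.4g}" if np.isfinite(v) else "-")
        lines.append(df.to_string(index=False))
    else:
        lines.append("(no ROI analyses)")
    lines.append("")
    lines.append("# Replication")
    if not bundle.replication:
        lines.append("(no replication pairs configured)")
    for (a, b, aname), overlap in bundle.replication.items():
        binary = np.nan_to_num(overlap.grid) > 0.5
        labeled, n_clusters = ndimage.label(binary)
        lines.append(f"{a} x {b} [{aname}]:")
        if n_clusters == 0:
            lines.append("  no replicated voxels")
            continue
        coms = ndimage.center_of_mass(binary, labeled, range(1, n_clusters + 1))
        for k, com in enumerate(coms, start=1):
            size = int((labeled == k).sum())
            com_str = ", ".join(f"{c:.1f}" for c in com)
            lines.append(f"  cluster {k}: {size} voxels, center of mass ({com_str})")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------

def _parse_analysis(name: str, d: Mapping) -> DecodingSpec:
    if "train_modality" in d and "test_modality" in d:
        return DecodingSpec.cross_modal(
            d["train_modality"], d["test_modality"],
            label_column=d.get("label_column", "emotion"),
        )
    return DecodingSpec.within_modality(
        d["modality"], label_column=d.get("label_column", "emotion"),
    )


def _parse_synthetic(d: Mapping) -> SyntheticConfig:
    d = dict(d)
    rois = d.pop("rois", None)
    roi_specs = ()
    if rois:
        roi_specs = tuple(
            cuboid_roi(r["name"], r["corner"], r["size"]) for r in rois
        )
    return SyntheticConfig(roi_specs=roi_specs, **{
        k: (tuple(v) if k == "grid_dims" else v) for k, v in d.items()
    })


def load_experiment_config(path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config YAML must be a mapping")
    try:
        cohorts = tuple(
            CohortSpec(
                name=c["name"],
                synthetic=_parse_synthetic(c["synthetic"]) if "synthetic" in c else None,
                paths=tuple(c["paths"]) if "paths" in c else None,
                derive_seed=c.get("derive_seed", True),
            )
            for c in raw["cohorts"]
        )
        analyses = table1_analyses()
        if "analyses" in raw:
            analyses = {name: _parse_analysis(name, d)
                        for name, d in raw["analyses"].items()}
        inference = InferenceConfig(**raw.get("inference", {}))
        searchlight = None
        if "searchlight" in raw:
            sl = dict(raw["searchlight"])
            if "analyses" in sl:
                sl["analyses"] = tuple(sl["analyses"])
            searchlight = SearchlightSettings(**sl)
        replication = None
        if "replication" in raw:
            rp = dict(raw["replication"])
            rconf = ReplicationConfig(**rp.pop("config", {}))
            replication = ReplicationPlan(
                pairs=tuple(tuple(p) for p in rp.get("pairs", ())),
                config=rconf,
                analyses=tuple(rp.get("analyses",
                                      ReplicationPlan().analyses)),
            )
        return ExperimentConfig(
            cohorts=cohorts,
            analyses=analyses,
            rois=tuple(raw.get("rois", ("planted",))),
            searchlight=searchlight,
            inference=inference,
            replication=replication,
            output_dir=raw.get("output_dir", "emodecode-results"),
            seed=int(raw.get("seed", 0)),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"invalid experiment config: {exc}") from exc
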