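"""End-to-end pipeline: configuration, subject loop, group stage, manifest.

The subject loop applies, in fixed order: drop initial volumes -> nuisance
regression -> band-pass (lFCD branch only) -> local statistic -> whole-brain
mean normalization -> Gaussian smoothing. The group stage builds the design,
fits the voxelwise GLM, applies BH-FDR and the cluster-extent filter.

``run_pipeline`` is the file-based entry point used by the CLI; it writes a
JSON run manifest (config hash, package and library versions, per-subject
QC, exclusions, output checksums) that makes a run reproducible and
auditable. ``run_group_analysis`` is the in-memory equivalent used by the
validation harness and the examples.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .glmstats import StatResult, build_design, cluster_filter, fdr_threshold, fit_voxelwise
from .localfc import LocalFCMap, NeighborhoodScheme, foca_map, lfcd_map, normalize_map, tsnr_mask
from .preprocess import (
    MotionTrace,
    VolumeSeries,
    bandpass,
    build_nuisance,
    detrend_keep_mean,
    drop_initial_volumes,
    exclude_by_fd,
    mean_fd,
    regress_nuisance,
    smooth,
)

logger = logging.getLogger("lifespan_localfc")

__all__ = ["PipelineConfig", "compute_subject_maps", "run_group_analysis", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One YAML-serializable artifact holding every pipeline parameter.

    Defaults reproduce the reference analysis settings: correlation
    threshold r = 0.6, tSNR gate 50, band 0.01-0.08 Hz, 8 mm FWHM smoothing,
    FDR q = 0.05, cluster extent > 30 voxels, 5 dropped volumes.
    """

    input_dir: str = "."
    output_dir: str = "out"
    brain_mask: str = "mask_brain.nii.gz"
    wm_mask: str = "mask_wm.nii.gz"
    csf_mask: str = "mask_csf.nii.gz"
    cohort_table: str = "cohort.tsv"
    n_drop: int = 5
    band: tuple[float, float] = (0.01, 0.08)
    r_threshold: float = 0.6
    snr_threshold: float = 50.0
    connectivity: int = 26
    foca_cube: int = 3
    fwhm: float = 8.0
    statistic: str = "lfcd"
    model: str = "age_model"
    coefficient: str = "age"
    behavior_name: str | None = None
    q: float = 0.05
    min_cluster: int = 30
    head_radius: float = 50.0
    lfcd_mode: str = "seed_corr"
    foca_bandpass: bool = False  # FOCA branch omits filtering by default
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(d["band"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "band" in raw:
            raw = {**raw, "band": tuple(raw["band"])}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def compute_subject_maps(
    vol: VolumeSeries,
    motion: MotionTrace,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    statistic: str,
    config: PipelineConfig | None = None,
) -> LocalFCMap:
    """Run the subject-level branch for one statistic and return the
    normalized, smoothed map."""
    cfg = config or PipelineConfig()
    if statistic not in ("lfcd", "foca"):
        raise ValueError(f"unknown statistic {statistic!r}")
    v, m = drop_initial_volumes(vol, motion, cfg.n_drop)
    v = dataclasses.replace(v, data=v.data.astype(np.float32))  # pipeline speed dtype
    snr = tsnr_mask(detrend_keep_mean(v), cfg.snr_threshold)
    nuis = build_nuisance(v, m, wm_mask, csf_mask, recipe=statistic)
    v = regress_nuisance(v, nuis)
    if statistic == "lfcd" or cfg.foca_bandpass:
        v = bandpass(v, *cfg.band)
    scheme = NeighborhoodScheme(connectivity=cfg.connectivity, foca_cube=cfg.foca_cube)
    if statistic == "lfcd":
        m3 = lfcd_map(v, scheme, r_threshold=cfg.r_threshold, snr=snr, mode=cfg.lfcd_mode)
    else:
        m3 = foca_map(dataclasses.replace(v, mask=v.mask & snr), scheme)
    m3 = normalize_map(m3)
    return smooth(m3, cfg.fwhm)


def run_group_analysis(
    spec,
    statistic: str = "lfcd",
    coef: str = "age",
    model: str = "age_model",
    behavior_name: str | None = None,
    q: float = 0.05,
    min_cluster: int = 30,
    config: PipelineConfig | None = None,
    **config_overrides,
) -> dict:
    """In-memory cohort analysis on a synthetic CohortSpec.

    Simulates the cohort, runs the subject loop, applies FD-based exclusion,
    fits the requested model/coefficient, and returns the StatResult (with
    FDR mask and cluster table attached) plus the QC'd cohort table.
    """
    from .synthetic import cohort_phenotypes, generate_subject

    cfg = config or PipelineConfig(
        statistic=statistic, model=model, coefficient=coef,
        behavior_name=behavior_name, q=q, min_cluster=min_cluster,
        **config_overrides,
    )
    table = cohort_phenotypes(spec)
    wm, csf = spec.tissue_masks()
    # stream subjects: one 4D volume in memory at a time, keep only the 3D maps
    all_maps: list[LocalFCMap] = []
    fds: list[float] = []
    for i, age in enumerate(table["age"]):
        vol, motion = generate_subject(spec, float(age), i)
        fds.append(mean_fd(MotionTrace(motion.params[cfg.n_drop:]), cfg.head_radius))
        all_maps.append(compute_subject_maps(vol, motion, wm, csf, statistic, cfg))
    table["mean_fd"] = fds
    table = exclude_by_fd(table)
    maps = [m for m, inc in zip(all_maps, table["included"]) if inc]
    design = build_design(table, model=model, behavior_name=behavior_name)
    stat = fit_voxelwise(maps, design, coef)
    stat.fdr_mask = fdr_threshold(stat.p_map, q=q, mask=stat.mask)
    stat.clusters = cluster_filter(
        stat.fdr_mask, stat.t_map, min_size=min_cluster,
        connectivity=cfg.connectivity, affine=spec.affine,
    )
    return {"stat": stat, "cohort": table, "n_included": int(table["included"].sum())}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_mask(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based end-to-end run; returns (and writes) the run manifest.

    Per-subject failures are logged and skipped, leaving a nonzero
    ``n_failed`` in the manifest; fewer than 2 usable subjects aborts.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_path = in_dir / config.cohort_table
    if not cohort_path.exists():
        raise FileNotFoundError(f"cohort table not found: {cohort_path}")
    table = pd.read_csv(cohort_path, sep="\t")
    if len(table) == 0:
        raise ValueError("empty cohort table")
    brain = _load_mask(in_dir / config.brain_mask)
    wm = _load_mask(in_dir / config.wm_mask)
    csf = _load_mask(in_dir / config.csf_mask)

    outputs: list[Path] = []
    qc_rows = []
    maps: dict[str, LocalFCMap] = {}
    n_failed = 0
    for sid in table["subject_id"].astype(str):
        try:
            vol = VolumeSeries.from_nifti(in_dir / f"{sid}_bold.nii.gz", brain)
            motion = MotionTrace.from_file(in_dir / f"rp_{sid}.txt")
            _, m_dropped = drop_initial_volumes(vol, motion, config.n_drop)
            fd = mean_fd(m_dropped, config.head_radius)
            subj_map = compute_subject_maps(vol, motion, wm, csf, config.statistic, config)
            map_path = out_dir / f"{sid}_{config.statistic}.nii.gz"
            subj_map.save(map_path)
            outputs += [map_path, map_path.with_name(f"{sid}_{config.statistic}.json")]
            maps[sid] = subj_map
            qc_rows.append({"subject_id": sid, "mean_fd": fd, "processed": True})
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            logger.error("subject %s failed: %s", sid, exc)
            n_failed += 1
            qc_rows.append({"subject_id": sid, "mean_fd": np.nan, "processed": False})

    qc = pd.DataFrame(qc_rows)
    table = table.merge(qc, on="subject_id")
    processed = table[table["processed"]].copy()
    if len(processed) < 2:
        raise RuntimeError("fewer than 2 usable subjects; aborting")
    processed = exclude_by_fd(processed)
    qc_out = out_dir / "qc.tsv"
    processed[["subject_id", "mean_fd", "included"]].to_csv(qc_out, sep="\t", index=False)
    outputs.append(qc_out)

    design = build_design(processed, model=config.model, behavior_name=config.behavior_name)
    used_maps = [maps[sid] for sid in design.subject_ids]
    stat = fit_voxelwise(used_maps, design, config.coefficient)
    stat.fdr_mask = fdr_threshold(stat.p_map, q=config.q, mask=stat.mask)
    stat.clusters = cluster_filter(
        stat.fdr_mask, stat.t_map, min_size=config.min_cluster,
        connectivity=config.connectivity, affine=used_maps[0].affine,
    )
    affine = used_maps[0].affine
    for name, arr in (
        (f"group_{config.coefficient}_t.nii.gz", stat.t_map),
        (f"group_{config.coefficient}_p.nii.gz", stat.p_map),
        (f"group_{config.coefficient}_fdrmask.nii.gz", stat.fdr_mask.astype(np.uint8)),
    ):
        path = out_dir / name
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), str(path))
        outputs.append(path)
    clus_path = out_dir / f"group_{config.coefficient}_clusters.tsv"
    stat.clusters.to_csv(clus_path, sep="\t", index=False)
    outputs.append(clus_path)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_subjects": int(len(table)),
        "n_failed": n_failed,
        "n_included": int(processed["included"].sum()),
        "excluded_subjects": processed.loc[~processed["included"], "subject_id"].tolist(),
        "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in outputs},
        "status": "partial" if n_failed else "ok",
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
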