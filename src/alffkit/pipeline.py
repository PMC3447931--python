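"""End-to-end driver: synthesize (or load) a cohort, preprocess, compute
standardized ALFF, run group inference with cluster-level permutation FWE
(optionally GM-corrected), and correlate significant-cluster VOI means with
clinical variables.

Every run writes its resolved configuration and a structured log next to
the outputs, and is deterministic given the seeds it records.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import pandas as pd

from . import io as _io
from .alff import compute_alff, standardize_alff
from .clinical import CLINICAL_VARIABLES, correlate_vois
from .coords import WorldCoordinate, mni_to_talairach
from .inference import (
    GroupDesign,
    InferenceConfig,
    ancova_image_covariate,
    extract_clusters,
    permutation_cluster_fwe,
)
from .preprocess import bandpass_run, discard_initial, motion_qc, smooth_run
from .synth import Cohort, SynthConfig, generate_cohort
from .types import BandSpec, BrainMask, InputError, ScalarMap

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: Path
    synth: Optional[SynthConfig] = None
    data_dir: Optional[Path] = None
    discard: int = 10
    fwhm_mm: float = 8.0
    band: BandSpec = field(default_factory=BandSpec)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    gm_covariate: bool = False
    enforce_motion_qc: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.data_dir is None):
            raise InputError("provide exactly one of synth config or data_dir")


@dataclass
class PipelineResult:
    malff_maps: List[ScalarMap]
    design: GroupDesign
    mask: BrainMask
    tmap: ScalarMap
    clusters: pd.DataFrame
    clusters_gm: Optional[pd.DataFrame]
    correlations: Optional[pd.DataFrame]
    excluded: List[str]
    out_dir: Path


def _resolve_cohort(config: PipelineConfig) -> Cohort:
    if config.synth is not None:
        return generate_cohort(config.synth)
    raise NotImplementedError(
        "directory loading is handled by the CLI via per-stage commands"
    )


def _talairach_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Annotate peak coordinates with their Talairach equivalents."""
    if table.empty:
        for col in ("tal_x_mm", "tal_y_mm", "tal_z_mm"):
            table[col] = pd.Series(dtype=float)
        return table
    tal = [
        mni_to_talairach(WorldCoordinate(r.peak_x_mm, r.peak_y_mm, r.peak_z_mm))
        for r in table.itertuples()
    ]
    table = table.copy()
    table["tal_x_mm"] = [round(c.x, 2) for c in tal]
    table["tal_y_mm"] = [round(c.y, 2) for c in tal]
    table["tal_z_mm"] = [round(c.z, 2) for c in tal]
    return table


def _write_resolved_config(config: PipelineConfig, out: Path) -> None:
    lines = []
    for f in dataclasses.fields(config):
        lines.append(f"{f.name}: {getattr(config, f.name)!r}")
    (out / "resolved_config.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis on a (synthetic) cohort and write a report tree.

    Outputs under ``out_dir``: per-subject mALFF maps, the group t-map,
    cluster tables (plain and, when requested, GM-corrected) with both MNI
    and Talairach peak coordinates, the VOI-clinical correlation table, the
    resolved configuration and a log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("alffkit")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> PipelineResult:
    _write_resolved_config(config, out)
    logger.info("pipeline start: seed=%d", config.seed)
    cohort = _resolve_cohort(config)
    mask = cohort.mask
    voxel_size = cohort.config.voxel_size_mm

    malff_maps: List[ScalarMap] = []
    kept_ids: List[str] = []
    kept_groups: List[str] = []
    kept_gm: List[ScalarMap] = []
    excluded: List[str] = []
    malff_dir = out / "malff"
    for sub in cohort.subjects:
        qc = motion_qc(sub.motion)
        if not qc.passed:
            logger.warning("subject %s fails motion QC on %s", sub.subject_id,
                           ",".join(qc.failing_axes))
            if config.enforce_motion_qc:
                excluded.append(sub.subject_id)
                continue
        run = discard_initial(sub.run, config.discard)
        run = smooth_run(run, config.fwhm_mm, voxel_size)
        run = bandpass_run(run, config.band)
        alff = compute_alff(run, mask, config.band)
        malff = standardize_alff(alff, mask)
        _io.write_nifti(malff_dir / f"{sub.subject_id}_malff.nii.gz", malff)
        malff_maps.append(malff)
        kept_ids.append(sub.subject_id)
        kept_groups.append(sub.group)
        kept_gm.append(sub.gm_map)
        logger.info("subject %s: mALFF computed", sub.subject_id)

    design = GroupDesign(kept_ids, kept_groups, image_covariates=kept_gm)
    clusters = permutation_cluster_fwe(malff_maps, design, mask, config.inference)
    clusters = _talairach_columns(clusters)
    clusters.to_csv(out / "clusters.csv", index=False)

    is_pat = design.is_patient
    tmap = _tmap_from(malff_maps, design, mask)
    _io.write_nifti(out / "group_tmap.nii.gz", tmap)

    clusters_gm = None
    if config.gm_covariate:
        tmap_gm = ancova_image_covariate(malff_maps, design, mask)
        _io.write_nifti(out / "group_tmap_gmcorr.nii.gz", tmap_gm)
        clusters_gm = extract_clusters(
            tmap_gm, config.inference.cluster_forming_t,
            config.inference.connectivity, config.inference.tail,
        )
        clusters_gm = _talairach_columns(clusters_gm)
        clusters_gm.to_csv(out / "clusters_gmcorr.csv", index=False)

    # VOIs = FWE-significant clusters; correlate with patient clinical scores
    correlations = None
    sig = clusters[clusters["p_corrected"] <= config.inference.cluster_alpha]
    if len(sig):
        vois = {}
        for row in sig.itertuples():
            voi_mask = _cluster_mask(tmap, row, config.inference)
            vois[f"cluster_{row.cluster_id}"] = voi_mask
            _io.write_nifti(out / f"voi_cluster_{row.cluster_id}.nii.gz", voi_mask)
        pat_maps = [m for m, p in zip(malff_maps, is_pat) if p]
        clin = cohort.clinical.set_index("subject_id").loc[
            [i for i, p in zip(kept_ids, is_pat) if p]
        ].reset_index()
        if len(pat_maps) >= 3:
            correlations = correlate_vois(pat_maps, vois, clin,
                                          variables=CLINICAL_VARIABLES)
            correlations.to_csv(out / "correlations.csv", index=False)
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    logger.info("pipeline done: %d clusters, %d significant, %d excluded",
                len(clusters), len(sig), len(excluded))
    return PipelineResult(
        malff_maps=malff_maps, design=design, mask=mask, tmap=tmap,
        clusters=clusters, clusters_gm=clusters_gm, correlations=correlations,
        excluded=excluded, out_dir=out,
    )


def _tmap_from(maps, design, mask) -> ScalarMap:
    from .inference import two_sample_tmap

    is_pat = design.is_patient
    return two_sample_tmap(
        [m for m, p in zip(maps, is_pat) if p],
        [m for m, p in zip(maps, is_pat) if not p],
        mask,
    )


def _cluster_mask(tmap: ScalarMap, row, inference: InferenceConfig) -> BrainMask:
    """Rebuild one cluster's voxel mask from its table row."""
    from scipy import ndimage

    from .inference import _structure

    binary = (row.sign * tmap.data) > inference.cluster_forming_t
    labels, _ = ndimage.label(binary, structure=_structure(inference.connectivity))
    lab = labels[row.peak_i, row.peak_j, row.peak_k]
    return BrainMask(labels == lab, tmap.affine)
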