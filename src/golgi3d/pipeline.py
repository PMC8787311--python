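"""End-to-end runs: simulate -> reconstruct -> classify -> morphometry.

Every run writes a manifest (config snapshot, seeds, input/output hashes,
per-stage provenance, tool version) so that re-running with an identical
manifest reproduces byte-identical outputs.  One seed in the config
propagates to all stochastic stages through independent spawned streams;
no stage ever reads global RNG state.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .classification import ClassifierRules, classify_volume, spine_density
from .image_io import ImageStack, VoxelSpacing, read_stack, write_stack
from .morphometry import (NeuronMorphology, SpindleCriteria, classify_spindle,
                          morphometry_report, read_swc, write_swc)
from .reconstruction import PipelineConfig, interpolate_z, reconstruct_spines
from .synthetic import (PhantomTruth, decorate_with_spines, render_stack,
                        standard_spine_fixture)

log = logging.getLogger("golgi3d")

__all__ = ["SimulateConfig", "RunConfig", "simulate", "run_all", "write_manifest",
           "spine_records_frame", "truth_table"]


SPINE_CSV_COLUMNS = [
    "spine_id", "x", "y", "z", "branch_arclen_um", "class", "neck_present",
    "neck_len_um", "neck_diam_um", "head_diam_um", "n_protrusions",
    "sphericity", "spinules",
]


class SimulateConfig(BaseModel):
    """Validated configuration of a phantom simulation."""

    kind: str = Field("standard_fixture", pattern="^(standard_fixture|custom)$")
    noise: str = Field("noiseless", pattern="^(noiseless|snr10)$")
    density_per_um: float = 0.8
    n_spines: Optional[int] = None
    class_mix: dict[str, float] = Field(
        default_factory=lambda: {"thin": 0.2, "stubby": 0.2, "wide": 0.2,
                                 "mushroom": 0.2, "ramified": 0.2})
    grouping: float = 0.0
    spacing: dict[str, float] = Field(
        default_factory=lambda: {"dx": 0.1, "dy": 0.1, "dz": 0.1})

    @field_validator("class_mix")
    @classmethod
    def _mix_sums_to_one(cls, v: dict[str, float]) -> dict[str, float]:
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        return v


class RunConfig(BaseModel):
    """Validated configuration of a full pipeline run."""

    pipeline: dict[str, Any] = Field(default_factory=dict)
    rules: dict[str, Any] = Field(default_factory=dict)
    vertical_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(**self.pipeline)

    def classifier_rules(self) -> ClassifierRules:
        return ClassifierRules(**self.rules)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir: Path, *, config: dict, seed: int | None,
                   stages: list[dict], outputs: list[Path]) -> Path:
    manifest = {
        "tool": "golgi3d",
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": stages,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def truth_table(truth: PhantomTruth) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(truth.spines):
        rows.append({
            "spine_id": i + 1, "class": s.class_label,
            "x": s.attachment[0], "y": s.attachment[1], "z": s.attachment[2],
            "arclen_um": s.position_arclen,
            "neck_len_um": s.neck_length, "neck_diam_um": s.neck_diameter,
            "head_diam_um": s.head_diameter, "n_heads": s.n_heads,
            "has_spinule": s.has_spinule, "length_um": s.length,
        })
    return pd.DataFrame(rows, columns=[
        "spine_id", "class", "x", "y", "z", "arclen_um", "neck_len_um",
        "neck_diam_um", "head_diam_um", "n_heads", "has_spinule", "length_um"])


def spine_records_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        f = r.features
        rows.append({
            "spine_id": r.spine_id, "x": r.attachment[0], "y": r.attachment[1],
            "z": r.attachment[2], "branch_arclen_um": r.branch_arclen,
            "class": r.class_label, "neck_present": f.neck_present,
            "neck_len_um": f.neck_length, "neck_diam_um": f.neck_diameter,
            "head_diam_um": f.head_diameter, "n_protrusions": f.n_protrusions,
            "sphericity": f.head_shape, "spinules": f.spinule_count,
        })
    return pd.DataFrame(rows, columns=SPINE_CSV_COLUMNS)


def simulate(config: SimulateConfig, seed: int, outdir: str | Path) -> dict:
    """Generate a phantom and write SWC + TIFF + truth CSV + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    if config.kind == "standard_fixture":
        truth, stack = standard_spine_fixture(seed=seed, noise=config.noise)
    else:
        from .synthetic import helix_segment
        segment = helix_segment()
        truth = decorate_with_spines(
            segment, config.density_per_um, config.class_mix,
            grouping=config.grouping, seed=seed, n_spines=config.n_spines)
        spacing = VoxelSpacing.from_dict(config.spacing)
        if config.noise == "noiseless":
            stack = render_stack(truth, spacing, seed=seed)
        else:
            stack = render_stack(truth, spacing, psf_sigma_xy=0.08,
                                 psf_sigma_z=0.16, speckle_density=0.2,
                                 illumination_gradient=0.1, noise_sd=15.0,
                                 seed=seed)
    swc_path = write_swc(truth.morphology, outdir / "phantom.swc")
    tif_path = write_stack(stack, outdir / "stack.tif")
    csv_path = outdir / "truth_spines.csv"
    truth_table(truth).to_csv(csv_path, index=False)
    stages = [{"stage": "simulate", "kind": config.kind, "noise": config.noise,
               "n_spines": len(truth.spines),
               "elapsed_s": round(time.perf_counter() - t0, 3)}]
    outputs = [swc_path, tif_path, Path(str(tif_path) + ".json"), csv_path]
    manifest = write_manifest(outdir, config=config.model_dump(), seed=seed,
                              stages=stages, outputs=outputs)
    log.info("simulate: %d spines, %s -> %s", len(truth.spines), config.kind, outdir)
    return {"truth": truth, "stack": stack, "manifest": manifest,
            "outputs": outputs}


def run_all(
    stack: ImageStack,
    config: RunConfig,
    outdir: str | Path,
    swc: NeuronMorphology | None = None,
    seed: int | None = None,
) -> dict:
    """reconstruct -> classify -> density (+ morphometry when SWC given).

    Writes spines.csv, report.json, mask.tif and manifest.json under
    ``outdir``; returns the in-memory results as well.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    t0 = time.perf_counter()
    cfg = config.pipeline_config()
    vol, summary = reconstruct_spines(stack, cfg)
    stages.append({"stage": "reconstruct", "summary": summary,
                   "elapsed_s": round(time.perf_counter() - t0, 3)})

    # classification runs on the pre-interpolation grid (original z sampling);
    # interpolation preserves original slices, so the restriction is exact
    analysis_vol = vol
    if cfg.zfactor > 1:
        from .reconstruction import BinaryVolume
        analysis_vol = BinaryVolume(
            vol.mask[::cfg.zfactor], stack.spacing, vol.provenance)

    t0 = time.perf_counter()
    rules = config.classifier_rules()
    if analysis_vol.mask.any():
        records, axis = classify_volume(analysis_vol, rules)
        density = spine_density(records, axis.length)
    else:
        records, axis = [], None
        density = {"density_per_um": 0.0, "band": "sparse", "n_spines": 0,
                   "dendrite_length_um": 0.0, "per_class": {}}
    stages.append({"stage": "classify", "n_spines": len(records),
                   "density_per_um": density["density_per_um"],
                   "elapsed_s": round(time.perf_counter() - t0, 3)})

    report: dict = {"reconstruction": summary, "density": density,
                    "provenance": vol.provenance}
    if swc is not None:
        if swc.soma_nodes() and swc.primary_dendrite_roots():
            mreport = morphometry_report(swc)
            ok, detail = classify_spindle(
                swc, SpindleCriteria(vertical_axis=config.vertical_axis))
            report["morphometry"] = mreport.as_dict()
            report["spindle_qualifier"] = detail
        else:
            # bare dendritic segment (no soma): polyline length only
            seg_len = sum(swc.edge_length(n) for n in swc.nodes
                          if n.parent != -1)
            report["morphometry"] = {"segment_length_um": seg_len,
                                     "n_nodes": len(swc.nodes)}

    mask_stack = ImageStack(
        (vol.mask * np.uint8(255)), vol.spacing, meta={"mask": True})
    mask_path = write_stack(mask_stack, outdir / "mask.tif")
    csv_path = outdir / "spines.csv"
    spine_records_frame(records).to_csv(csv_path, index=False)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=str))
    outputs = [mask_path, Path(str(mask_path) + ".json"), csv_path, report_path]
    manifest = write_manifest(outdir, config=config.model_dump(), seed=seed,
                              stages=stages, outputs=outputs)
    log.info("run_all: %d spines at %.2f /um -> %s", len(records),
             density["density_per_um"], outdir)
    return {"volume": vol, "records": records, "axis": axis, "density": density,
            "report": report, "manifest": manifest, "outputs": outputs}


def load_yaml_config(path: str | Path, model):
    """Load and validate a YAML config file against a pydantic model."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return model.model_validate(data)
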