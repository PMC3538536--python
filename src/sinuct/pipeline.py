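"""End-to-end pipeline: phantom -> acquisition -> preprocessing ->
reconstruction -> segmentation -> morphometry, as one configured, logged,
resumable run, plus recovery scoring against the phantom ground truth.

Every stage writes its artifacts into a subdirectory of the run directory
together with a manifest (stage name, parameters, SHA-256 of inputs and
outputs), so a rerun with the same config reproduces identical measurement
CSVs and each stage provably consumed only prior-stage files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from . import morphometry as morpho
from .config import RunConfig
from .errors import MatchingError
from .optics import acquire_dataset
from .phantom import (
    Phantom,
    add_thrombus,
    ground_truth_morphometry,
    make_sinusoid_phantom,
    read_phantom,
    tissue_cylinder_mask,
    write_phantom,
)
from .preprocess import edge_enhance, flat_dark_correct, ring_correct, smooth
from .recon import reconstruct_volume
from .segment import LabelVolume, segment_sinusoids, segment_thrombus

__all__ = ["run_pipeline", "compare_to_truth", "load_labels"]

logger = logging.getLogger(__name__)

STAGES = ("phantom", "acquire", "preprocess", "recon", "segment", "measure")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(stage_dir: Path, stage: str, params: dict, inputs: list[Path]) -> None:
    outputs = [
        p for p in sorted(stage_dir.rglob("*")) if p.is_file() and p.name != "manifest.json"
    ]
    manifest = {
        "stage": stage,
        "params": params,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": {str(p.relative_to(stage_dir)): _sha256(p) for p in outputs},
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig, resume: bool = False) -> Path:
    """Execute all stages; returns the run directory.

    With ``resume=True`` a stage whose manifest already exists and whose
    recorded parameters match the config is not recomputed.
    """
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("sinuct")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        _run_stages(config, run_dir, resume)
    except Exception as exc:  # persist the failure point, then re-raise
        (run_dir / "FAILED.json").write_text(
            json.dumps({"error": str(exc), "type": type(exc).__name__})
        )
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return run_dir


def _stage_fresh(stage_dir: Path, params: dict, resume: bool) -> bool:
    if not resume:
        return False
    manifest = stage_dir / "manifest.json"
    if not manifest.exists():
        return False
    recorded = json.loads(manifest.read_text()).get("params")
    return recorded == json.loads(json.dumps(params))


def _run_stages(config: RunConfig, run_dir: Path, resume: bool) -> None:
    pc = config.phantom
    phantom_dir = run_dir / "phantom"
    phantom_params = dataclasses.asdict(pc) | {"seed": config.seed}
    phantom_params["thrombus"] = {str(k): v for k, v in phantom_params["thrombus"].items()}
    if _stage_fresh(phantom_dir, phantom_params, resume):
        logger.info("phantom: resumed")
        phantom = read_phantom(phantom_dir)
    else:
        logger.info("phantom: generating grade=%s n=%d", pc.grade, pc.n_sinusoids)
        phantom = make_sinusoid_phantom(
            pc.grid_shape,
            pc.voxel_size_um,
            pc.grade,
            pc.n_sinusoids,
            pc.diameter_range_um,
            seed=config.seed,
        )
        for label_id, fraction in sorted(pc.thrombus.items()):
            phantom = add_thrombus(phantom, label_id, fraction, seed=config.seed + label_id)
        write_phantom(phantom, phantom_dir)
        truth = ground_truth_morphometry(phantom)
        pd.DataFrame([dataclasses.asdict(r) for r in truth]).to_csv(
            phantom_dir / "ground_truth.csv", index=False
        )
        _write_manifest(phantom_dir, "phantom", phantom_params, [])

    acquire_dir = run_dir / "acquire"
    geo_params = dataclasses.asdict(config.geometry)
    if _stage_fresh(acquire_dir, geo_params, resume):
        logger.info("acquire: resumed")
        pset = _io.read_projection_set(acquire_dir)
    else:
        logger.info(
            "acquire: %d angles over %.0f deg, flats=%d darks=%d noise=%s",
            config.geometry.n_angles,
            config.geometry.angular_range_deg,
            config.geometry.n_flats,
            config.geometry.n_darks,
            config.geometry.noise,
        )
        pset = acquire_dataset(phantom, config.geometry)
        _io.write_projection_set(pset, acquire_dir)
        _write_manifest(
            acquire_dir, "acquire", geo_params, sorted(phantom_dir.glob("*.tif"))
        )

    pre_dir = run_dir / "preprocess"
    pre_params = dataclasses.asdict(config.preprocess)
    logger.info("preprocess: flat/dark, smooth sigma=%.2f, rings=%s",
                config.preprocess.smooth_strength, config.preprocess.ring_correct)
    sinos = flat_dark_correct(pset)
    if config.preprocess.smooth_strength > 0:
        sinos = smooth(sinos, config.preprocess.smooth_strength)
    if config.preprocess.ring_correct:
        sinos = ring_correct(sinos, config.preprocess.ring_window)
    pre_dir.mkdir(parents=True, exist_ok=True)
    _io.write_stack(pre_dir / "sinograms.tif", sinos.data.astype(np.float32))
    _write_manifest(pre_dir, "preprocess", pre_params, sorted(acquire_dir.glob("*.tif")))

    recon_dir = run_dir / "recon"
    logger.info("recon: FBP filter=%s", config.recon.filter_name)
    volume = reconstruct_volume(sinos, config.recon.filter_name)
    if config.preprocess.edge_enhance_amount > 0:
        enhanced = np.stack(
            [
                edge_enhance(
                    s,
                    config.preprocess.edge_enhance_amount,
                    config.preprocess.edge_enhance_radius,
                )
                for s in volume.data
            ]
        )
        _io.write_stack(recon_dir / "volume_enhanced.tif", enhanced.astype(np.float32))
    recon_dir.mkdir(parents=True, exist_ok=True)
    _io.write_stack(recon_dir / "volume.tif", volume.data.astype(np.float32))
    _io.write_json(recon_dir / "volume.json", {"voxel_size_um": volume.voxel_size})
    _write_manifest(
        recon_dir,
        "recon",
        dataclasses.asdict(config.recon),
        [pre_dir / "sinograms.tif"],
    )

    seg_dir = run_dir / "segment"
    sc = config.segment
    logger.info("segment: min_voxels=%d", sc.min_voxels)
    roi = (
        tissue_cylinder_mask(volume.data.shape, margin=sc.roi_margin)
        if sc.use_cylinder_roi
        else None
    )
    labels = segment_sinusoids(
        volume,
        min_voxels=sc.min_voxels,
        median_size=sc.median_size,
        tissue_erosion=sc.tissue_erosion,
        tissue_mask=roi,
    )
    labels = segment_thrombus(
        volume, labels, sc.thrombus_brightness_sigma, sc.thrombus_min_voxels
    )
    seg_dir.mkdir(parents=True, exist_ok=True)
    _io.write_stack(seg_dir / "labels.tif", labels.labels.astype(np.uint16))
    _io.write_stack(seg_dir / "thrombus.tif", labels.thrombus_mask.astype(np.uint8))
    _io.write_json(seg_dir / "labels.json", {"voxel_size_um": labels.voxel_size})
    _write_manifest(
        seg_dir, "segment", dataclasses.asdict(sc), [recon_dir / "volume.tif"]
    )

    measure_dir = run_dir / "measure"
    measure_dir.mkdir(parents=True, exist_ok=True)
    records = morpho.measure_all(labels)
    logger.info("measure: %d sinusoid(s)", len(records))
    morpho.records_to_dataframe(records).to_csv(
        measure_dir / "sinusoids.csv", index=False
    )
    if records:
        summary = morpho.summarize(records)
        morpho.summary_to_dataframe(summary).to_csv(
            measure_dir / "summary.csv", index=False
        )
        (measure_dir / "summary.txt").write_text(morpho.format_summary(summary) + "\n")
    else:
        logger.info("measure: no records; summary skipped")
    _write_manifest(
        measure_dir, "measure", {}, [seg_dir / "labels.tif", seg_dir / "thrombus.tif"]
    )


def load_labels(run_dir: str | Path) -> LabelVolume:
    """Load the segmentation stage output of a run."""
    run_dir = Path(run_dir)
    meta = _io.read_json(run_dir / "segment" / "labels.json")
    return LabelVolume(
        labels=_io.read_stack(run_dir / "segment" / "labels.tif").astype(np.int32),
        thrombus_mask=_io.read_stack(run_dir / "segment" / "thrombus.tif").astype(bool),
        voxel_size=float(meta["voxel_size_um"]),
    )


def _overlap_matrix(truth: np.ndarray, found: np.ndarray) -> dict[tuple[int, int], int]:
    both = (truth > 0) & (found > 0)
    pairs, counts = np.unique(
        np.stack([truth[both], found[both]]), axis=1, return_counts=True
    )
    return {
        (int(t), int(f)): int(c) for (t, f), c in zip(pairs.T, counts)
    }


def compare_to_truth(
    run_dir: str | Path, phantom: Phantom | None = None
) -> dict:
    """Score a run against the phantom ground truth.

    Recovered labels are matched to true labels by maximal voxel overlap
    (id-agnostic); the report holds per-match Dice and relative descriptor
    errors plus cohort medians, and is written to ``recovery.json`` in the
    run directory.
    """
    run_dir = Path(run_dir)
    if phantom is None:
        phantom = read_phantom(run_dir / "phantom")
    labels = load_labels(run_dir)
    truth_records = {r.label_id: r for r in ground_truth_morphometry(phantom)}
    found_records = {
        r.label_id: r for r in morpho.measure_all(labels)
    }
    overlap = _overlap_matrix(phantom.label_volume, labels.labels)
    if not overlap:
        raise MatchingError("no voxel overlap between recovered and true labels")
    true_sizes = np.bincount(phantom.label_volume.ravel())
    found_sizes = np.bincount(labels.labels.ravel())

    matches = []
    for true_id, rec in truth_records.items():
        candidates = {f: c for (t, f), c in overlap.items() if t == true_id}
        if not candidates:
            matches.append({"true_label": true_id, "matched": None})
            continue
        found_id = max(candidates, key=lambda f: (candidates[f], -f))
        inter = candidates[found_id]
        dice = 2.0 * inter / (true_sizes[true_id] + found_sizes[found_id])
        found = found_records[found_id]

        def rel(measured, true):
            return abs(measured - true) / true if true else float("nan")

        matches.append(
            {
                "true_label": true_id,
                "matched": found_id,
                "dice": float(dice),
                "volume_rel_err": rel(found.volume, rec.true_volume),
                "min_diameter_rel_err": rel(found.min_diameter, rec.true_min_diameter),
                "max_diameter_rel_err": rel(found.max_diameter, rec.true_max_diameter),
                "surface_area_rel_err": rel(found.surface_area, rec.true_surface_area),
                "thrombus_fraction_err_pct": abs(
                    found.thrombus_fraction - 100.0 * rec.true_thrombus_fraction
                ),
            }
        )
    matched = [m for m in matches if m["matched"] is not None]
    report = {
        "n_true": len(truth_records),
        "n_found": labels.n_labels,
        "n_matched": len(matched),
        "matches": matches,
        "median": {
            key: float(np.median([m[key] for m in matched]))
            for key in (
                "dice",
                "volume_rel_err",
                "min_diameter_rel_err",
                "max_diameter_rel_err",
                "surface_area_rel_err",
            )
        }
        if matched
        else {},
    }
    _io.write_json(run_dir / "recovery.json", report)
    return report
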