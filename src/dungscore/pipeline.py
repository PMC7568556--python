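"""Batch orchestration: manifests, full-pipeline runs, reports and diagnostics.

A *manifest* maps sample ids to per-band image lists and rig configs::

    samples:
      - id: cow-07
        bands:
          VIS: {rig: rig_vis.yaml, images: [a0.png, a1.png, a2.png, a3.png]}
          NIR: {rig: rig_nir.yaml, images: [b0.png, b1.png, b2.png, b3.png]}

``run_pipeline`` loads every sample, scores the batch (segmentation ->
metrics -> batch normalisation -> total score -> rank), and writes a CSV
report plus per-sample diagnostic images and a JSON log that records the
full configuration, so a run is reproducible from the log and inputs alone.
Per-sample failures are recorded and the batch continues.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from skimage.morphology import convex_hull_image

from .errors import DungscoreError, ManifestError
from .io import load_stack, write_intensity_image
from .metrics import (
    DEFAULT_BAND_ASSIGNMENT,
    BatchResult,
    FilterParams,
    Sample,
    compute_raw_metrics,
    score_batch,
)
from .photometric import solve_ps
from .segmentation import SegmentationParams, min_image

CSV_SCHEMA_VERSION = 1
CSV_COLUMNS = ["sample_id", "border_raw", "shininess_raw", "normal_raw",
               "border", "shininess", "normal", "total", "rank"]


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    bands: dict[str, tuple[str, list[str]]]  # band -> (rig path, image paths)


@dataclass(frozen=True)
class SampleManifest:
    entries: list[ManifestEntry]


def load_manifest(path: str | os.PathLike) -> SampleManifest:
    """Parse and validate a YAML manifest (unique ids, band structure)."""
    base = Path(path).parent
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "samples" not in doc:
        raise ManifestError(f"{path}: manifest must be a mapping with a 'samples' list")
    entries = []
    seen: set[str] = set()
    for item in doc["samples"]:
        sid = str(item.get("id", ""))
        if not sid:
            raise ManifestError(f"{path}: sample without an id")
        if sid in seen:
            raise ManifestError(f"{path}: duplicate sample id {sid!r}")
        seen.add(sid)
        bands = {}
        for band, entry in (item.get("bands") or {}).items():
            if "rig" not in entry or "images" not in entry:
                raise ManifestError(f"{path}: sample {sid} band {band} needs rig + images")
            bands[str(band).upper()] = (
                str(base / entry["rig"]),
                [str(base / p) for p in entry["images"]],
            )
        if not bands:
            raise ManifestError(f"{path}: sample {sid} lists no bands")
        entries.append(ManifestEntry(sample_id=sid, bands=bands))
    return SampleManifest(entries=entries)


def _load_sample(entry: ManifestEntry) -> Sample:
    stacks = {band: load_stack(paths, rig) for band, (rig, paths) in entry.bands.items()}
    if len(stacks) == 1:
        warnings.warn(
            f"sample {entry.sample_id}: single band supplied; NIR is preferred for "
            "the normal metric and VIS for border/shininess",
            stacklevel=2,
        )
    return Sample(sample_id=entry.sample_id, stacks=stacks)


def write_diagnostics(sample: Sample, out_dir: str | os.PathLike,
                      filter_params: FilterParams | None = None,
                      seg_params: SegmentationParams | None = None) -> None:
    """Write per-sample diagnostic PNGs: I_min, mask + hull, I', and N''."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _, mask = compute_raw_metrics(sample, filter_params, seg_params)
    stack = sample.stacks.get("VIS") or next(iter(sample.stacks.values()))
    write_intensity_image(min_image(stack), out / f"{sample.sample_id}_imin.png")
    hull = convex_hull_image(mask.mask)
    overlay = np.where(mask.mask, 1.0, np.where(hull, 0.5, 0.0))
    write_intensity_image(overlay, out / f"{sample.sample_id}_mask_hull.png")
    iprime = stack.images.max(axis=0) - stack.images.min(axis=0)
    write_intensity_image(iprime, out / f"{sample.sample_id}_iprime.png")
    nstack = sample.stacks.get("NIR") or stack
    surface = solve_ps(nstack)
    params = filter_params or FilterParams()
    # rebuild the roughness image N'' for visual inspection
    from .metrics import local_std_filter, weighted_median_filter  # cycle-free

    from scipy.ndimage import gaussian_filter

    nz = surface.nz
    nprime = np.abs(gaussian_filter(nz, params.effective_sigma, mode="reflect") - nz)
    ndouble = local_std_filter(
        weighted_median_filter(nprime, params.effective_median_neighbourhood,
                               params.median_centre_weight),
        params.effective_sdf_radius,
    )
    top = ndouble.max()
    write_intensity_image(ndouble / top if top > 0 else ndouble,
                          out / f"{sample.sample_id}_nsdf.png")


def run_pipeline(
    manifest: SampleManifest,
    out_dir: str | os.PathLike,
    filter_params: FilterParams | None = None,
    seg_params: SegmentationParams | None = None,
    band_assignment=DEFAULT_BAND_ASSIGNMENT,
    squared: bool = True,
    diagnostics: bool = True,
) -> BatchResult:
    """Score every manifest sample; write scores.csv, diagnostics and run_log.json.

    Returns the :class:`BatchResult`; the run succeeded if at least one
    sample scored (``result.metrics`` non-empty).  Load failures and scoring
    failures alike land in ``result.errors`` keyed by sample id.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples: list[Sample] = []
    load_errors: dict[str, str] = {}
    for entry in manifest.entries:
        try:
            samples.append(_load_sample(entry))
        except (DungscoreError, OSError) as exc:
            load_errors[entry.sample_id] = f"{type(exc).__name__}: {exc}"
    result = score_batch(samples, filter_params, seg_params, band_assignment,
                         squared=squared)
    result.errors.update(load_errors)
    frame = result.to_frame()[CSV_COLUMNS]
    frame.to_csv(out / "scores.csv", index=False, float_format="%.10g")
    if diagnostics:
        failed = set(result.errors)
        for sample in samples:
            if sample.sample_id not in failed:
                write_diagnostics(sample, out / "diagnostics", filter_params, seg_params)
    fp = filter_params or FilterParams()
    sp = seg_params or SegmentationParams()
    log = {
        "csv_schema_version": CSV_SCHEMA_VERSION,
        "filter_params": dataclasses.asdict(fp),
        "segmentation_params": dataclasses.asdict(sp),
        "band_assignment": dict(band_assignment),
        "score_variant": "S_N/(S_B*S_S^2)" if squared else "S_N/(S_B*S_S)",
        "n_scored": len(result.metrics),
        "errors": result.errors,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return result
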