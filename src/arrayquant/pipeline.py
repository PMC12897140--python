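"""End-to-end orchestration: scan image -> per-analyte value table.

The canonical run: the first scan of a batch is detected and gridded into
a :class:`~arrayquant.grid_processing.GridTemplate`; every scan (including
the first) is then measured at template well positions.  Scans after the
first are registered onto the template by the alignment stage.  All
geometry happens in the rotation-corrected frame; measured positions are
rotated back so intensities are always sampled from the original pixels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blob_detection import Blob, DetectionParams, detect
from .errors import DetectionError
from .grid_processing import (
    GridTemplate,
    RotationEstimate,
    _rotate_xy,
    build_grid,
    correct_rotation,
)
from .image_io import ArrayImage, read_image
from .intensity_measurement import (
    AnalyteMap,
    collapse_duplicates,
    measure_wells,
    normalize_controls,
    render_overlay,
)
from .template_alignment import AlignmentResult, align


@dataclass
class ImageResult:
    """Everything produced for one scan."""

    template: GridTemplate
    rotation: RotationEstimate
    alignment: AlignmentResult | None
    positions: np.ndarray  # well positions in the original image frame
    intensity: pd.DataFrame  # per-well raw/normalized/log_norm
    analytes: pd.DataFrame  # collapsed per-analyte values


def well_positions_in_image(
    template: GridTemplate,
    rotation: RotationEstimate,
    alignment: AlignmentResult | None,
) -> np.ndarray:
    """Template wells -> original image coordinates.

    Applies the alignment (if any) in the rotation-corrected frame, then
    undoes the rotation correction.
    """
    pos = template.positions()
    if alignment is not None:
        pos = alignment.predict(pos)
    if rotation.applied:
        pos = _rotate_xy(pos, -rotation.angle, np.asarray(rotation.center))
    return pos


def locate_wells(
    image: ArrayImage,
    template: GridTemplate,
    params: DetectionParams = DetectionParams(),
    seed: int = 0,
) -> tuple[np.ndarray, RotationEstimate, AlignmentResult]:
    """Localize every template well on a new scan.

    Returns positions in the original image frame (one per template well,
    in template well order) plus the rotation and alignment diagnostics.
    """
    blobs = detect(image, params)
    if len(blobs) < 4:
        raise DetectionError(f"only {len(blobs)} spots detected")
    corrected, rot = correct_rotation(blobs)
    result = align(template, corrected, seed=seed)
    return well_positions_in_image(template, rot, result), rot, result


def process_image(
    image: ArrayImage | str | Path,
    amap: AnalyteMap,
    template: GridTemplate | None = None,
    params: DetectionParams = DetectionParams(),
    seed: int = 0,
    weighting: str = "flat",
    invert: bool = False,
) -> ImageResult:
    """Run the full four-stage pipeline on one scan.

    With ``template=None`` the scan builds its own template (detect ->
    grid); otherwise the stored template is aligned onto the scan.
    """
    if not isinstance(image, ArrayImage):
        image = read_image(image, invert=invert)
    blobs = detect(image, params)
    if len(blobs) < 4:
        raise DetectionError(f"only {len(blobs)} spots detected")
    if template is None:
        template, rot = build_grid(blobs, control_spec=amap.control_spec())
        alignment = None
    else:
        corrected, rot = correct_rotation(blobs)
        alignment = align(template, corrected, seed=seed)
    positions = well_positions_in_image(template, rot, alignment)
    raw = measure_wells(image, template, positions=positions, weighting=weighting)
    intensity = normalize_controls(raw, amap)
    analytes = collapse_duplicates(intensity, amap)
    return ImageResult(
        template=template,
        rotation=rot,
        alignment=alignment,
        positions=positions,
        intensity=intensity,
        analytes=analytes,
    )


def run_pipeline(
    images: list[ArrayImage | str | Path],
    amap: AnalyteMap,
    template: GridTemplate | None = None,
    params: DetectionParams = DetectionParams(),
    seed: int = 0,
    weighting: str = "flat",
    invert: bool = False,
    outdir: str | Path | None = None,
) -> tuple[list[ImageResult], GridTemplate]:
    """Process a batch of scans against one shared template.

    If no template is given the first image builds it.  With ``outdir``
    set, per-image intensity/analyte CSVs, QC overlays and a provenance
    record (parameters, seeds, version) are written there.
    """
    if not images:
        raise DetectionError("no images to process")
    results: list[ImageResult] = []
    for i, im in enumerate(images):
        res = process_image(
            im,
            amap,
            template=template,
            params=params,
            seed=seed + i,
            weighting=weighting,
            invert=invert,
        )
        template = res.template
        results.append(res)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        template.save(outdir / "template.txt")
        for i, (im, res) in enumerate(zip(images, results)):
            stem = Path(im).stem if not isinstance(im, ArrayImage) else f"image_{i:02d}"
            res.intensity.to_csv(outdir / f"{stem}_wells.csv", index=False)
            res.analytes.to_csv(outdir / f"{stem}_analytes.csv", index=False)
            img = im if isinstance(im, ArrayImage) else read_image(im, invert=invert)
            render_overlay(
                img,
                template,
                res.alignment,
                outdir / f"{stem}_overlay.png",
            )
        provenance = {
            "version": __version__,
            "seed": seed,
            "weighting": weighting,
            "invert": invert,
            "detection_params": {
                k: getattr(params, k)
                for k in (
                    "contrast_lower",
                    "contrast_upper",
                    "min_sigma",
                    "max_sigma",
                    "num_sigma",
                    "threshold",
                    "radius_filter",
                    "cluster_eps",
                    "cluster_min_pts",
                )
            },
            "n_images": len(images),
        }
        provenance["config_hash"] = hashlib.sha256(
            json.dumps(provenance, sort_keys=True).encode()
        ).hexdigest()[:16]
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    return results, template
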