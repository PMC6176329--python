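"""Image and table I/O plus the end-to-end pipeline driver.

Coordinate convention used everywhere in the package: 0-based ``(row, col)``
pixel indices, boxes as half-open ``[top, top+height) x [left, left+width)``.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import cascade as _cascade
from . import drlse as _drlse
from . import spine as _spine
from .config import PipelineConfig
from .spine import CurvatureReport

logger = logging.getLogger("spinecurve")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ImagePlane:
    """A 2-D grayscale slice with view label and pixel spacing (mm/px)."""

    pixels: np.ndarray  # float64 in [0, 1]
    spacing_mm: float = 1.0
    view: str | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def read_image(path: str | Path) -> ImagePlane:
    """Read a PNG/TIFF grayscale image or a single-frame DICOM slice.

    Intensities are rescaled to [0, 1] (integer images by their dtype's full
    range, DICOM by min-max after slope/intercept).  Pixel spacing comes
    from DICOM metadata when present; otherwise 1.0 with a logged warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", ""):
        return _read_dicom(path)
    if suffix not in (".png", ".tif", ".tiff"):
        raise PipelineError(f"read_image: unsupported format {suffix!r}")
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise PipelineError(f"read_image: cannot read {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise PipelineError(f"read_image: {path} is not a 2-D image")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
        if arr.max() > 1.0:
            arr = arr / arr.max()
    logger.warning("no pixel spacing metadata in %s; assuming 1.0 mm/px", path.name)
    return ImagePlane(pixels=np.clip(arr, 0.0, 1.0), spacing_mm=1.0)


def _read_dicom(path: Path) -> ImagePlane:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:
        raise PipelineError(f"read_image: cannot read DICOM {path}: {exc}") from exc
    if arr.ndim != 2:
        raise PipelineError(f"read_image: {path} is multi-frame; a single slice is required")
    arr = arr.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    lo, hi = arr.min(), arr.max()
    arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is not None:
        spacing_mm = float(spacing[0])
    else:
        logger.warning("DICOM %s has no PixelSpacing; assuming 1.0 mm/px", path.name)
        spacing_mm = 1.0
    return ImagePlane(pixels=arr, spacing_mm=spacing_mm)


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Binary mask as a 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def write_label_image(path: str | Path, masks) -> None:
    """Combined labeled mask: pixel value = detection number (0 background)."""
    out = None
    for m in masks:
        if out is None:
            out = np.zeros(m.mask.shape, dtype=np.uint8)
        out[m.mask > 0] = m.number
    if out is not None:
        iio.imwrite(Path(path), out)


# ---------------------------------------------------------------------------
# Tables and reports
# ---------------------------------------------------------------------------


def write_detections(path: str | Path, detections) -> None:
    pd.DataFrame(
        [
            {
                "number": d.number,
                "top": d.top,
                "left": d.left,
                "height": d.height,
                "width": d.width,
                "score": d.score,
            }
            for d in detections
        ],
        columns=["number", "top", "left", "height", "width", "score"],
    ).to_csv(path, index=False)


def read_detections(path: str | Path) -> list:
    df = pd.read_csv(path)
    return [
        _cascade.Detection(
            number=int(r.number),
            top=int(r.top),
            left=int(r.left),
            height=int(r.height),
            width=int(r.width),
            score=float(r.score),
        )
        for r in df.itertuples()
    ]


def write_centroids(path: str | Path, numbers, centroids) -> None:
    pd.DataFrame(
        {
            "number": list(numbers),
            "row": [c[0] for c in centroids],
            "col": [c[1] for c in centroids],
        }
    ).to_csv(path, index=False)


def read_centroids(path: str | Path) -> tuple[list[int], list[tuple[float, float]]]:
    df = pd.read_csv(path)
    return (
        [int(n) for n in df["number"]],
        [(float(r), float(c)) for r, c in zip(df["row"], df["col"])],
    )


def write_report(path: str | Path, report: CurvatureReport) -> None:
    Path(path).write_text(yaml.safe_dump(report.to_dict(), sort_keys=False))


def read_report(path: str | Path) -> CurvatureReport:
    data = yaml.safe_load(Path(path).read_text())
    return CurvatureReport(
        phi=float(data["phi_degrees"]),
        view=data["view"],
        region=data["region"],
        diagnosis=data["diagnosis"],
        rule=data["rule"],
        r_squared=data.get("r_squared"),
        rmse=data.get("rmse"),
        n_centroids=data.get("n_centroids"),
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    image_path: str | Path,
    model_path: str | Path,
    view: str,
    region: str | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> CurvatureReport:
    """Detect -> segment -> analyze on one image, writing all artifacts.

    Raises :class:`PipelineError` when fewer than 3 vertebrae are detected
    (too few centroids for a spinal curve).  When ``out_dir`` is given, the
    detections CSV, per-vertebra mask PNGs, a combined label image, the
    centroids CSV and the report are written there.
    """
    config = config or PipelineConfig()
    image = read_image(image_path)
    model = _cascade.load_model(model_path)

    t0 = time.perf_counter()
    detections = _cascade.detect(model, image.pixels, config.detector)
    logger.info(
        "detect: %d windows accepted in %.2fs", len(detections), time.perf_counter() - t0
    )
    if len(detections) < 3:
        raise PipelineError(
            f"detect: only {len(detections)} vertebrae found; need >= 3 for a curve"
        )

    t0 = time.perf_counter()
    masks = _drlse.segment(image.pixels, detections, config.levelset)
    n_nonempty = sum(1 for m in masks if m.mask.any())
    logger.info(
        "segment: %d/%d non-empty masks in %.2fs",
        n_nonempty,
        len(masks),
        time.perf_counter() - t0,
    )

    try:
        report = _spine.analyze(masks, view=view, region=region, degree=config.curve_degree)
    except ValueError as exc:
        raise PipelineError(f"analyze: {exc}") from exc
    logger.info("analyze: phi = %.2f deg -> %s", report.phi, report.diagnosis)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_detections(out / "detections.csv", detections)
        numbers, centroids = [], []
        for m in masks:
            write_mask(out / f"mask_{m.number:02d}.png", m.mask)
            if m.mask.any():
                numbers.append(m.number)
                centroids.append(_spine.extract_centroid(m.mask))
        write_label_image(out / "labels.png", masks)
        write_centroids(out / "centroids.csv", numbers, centroids)
        write_report(out / "report.yaml", report)
    return report
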