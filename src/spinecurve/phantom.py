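"""Synthetic spine phantoms with analytic ground truth, plus evaluation metrics.

A phantom is a noisy grayscale image containing a column of bright,
vertebra-like blobs (superellipses) whose centers lie on an analytic
centerline ``col = base + offset(row)``, with ``offset`` a polynomial in the
cranio-caudal (row) coordinate.  Because the centerline is analytic, the
ground-truth tangent angle between the terminal vertebrae is known in closed
form, so every downstream stage — detection, segmentation, centroid
extraction, curvature measurement, diagnosis — can be validated without any
external imaging data.

The module also hosts the detection / centroid / ROC evaluation metrics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from numpy.polynomial import polynomial as npoly
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .config import DetectorConfig, FeatureConfig, PipelineConfig


class PhantomSpecError(ValueError):
    """Raised when a phantom specification cannot be rendered."""


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of one synthetic spine image.

    ``centerline_coeffs`` are ascending polynomial coefficients of the
    lateral offset (in pixels, relative to the image's center column) as a
    function of the absolute row coordinate.
    """

    n_vertebrae: int = 7
    centerline_coeffs: tuple[float, ...] = (0.0,)
    vertebra_size: tuple[int, int] = (24, 20)  # (height, width) px
    spacing: float = 34.0  # px between centers along the centerline
    fg_intensity: float = 0.75
    bg_intensity: float = 0.25
    noise_sd: float = 0.05
    image_shape: tuple[int, int] = (256, 192)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 2:
            raise PhantomSpecError("need at least 2 vertebrae")
        if self.fg_intensity <= self.bg_intensity:
            raise PhantomSpecError("fg_intensity must exceed bg_intensity")
        if self.spacing <= 0:
            raise PhantomSpecError("spacing must be positive")
        h, w = self.vertebra_size
        if h < 4 or w < 4:
            raise PhantomSpecError("vertebra_size too small")

    def to_yaml(self, path: str | Path) -> None:
        def plain(v):
            if isinstance(v, tuple):
                return [plain(x) for x in v]
            if isinstance(v, np.integer):
                return int(v)
            if isinstance(v, np.floating):
                return float(v)
            return v

        data = {k: plain(v) for k, v in dataclasses.asdict(self).items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        data = yaml.safe_load(Path(path).read_text())
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise PhantomSpecError(f"unknown phantom keys: {sorted(unknown)}")
        data = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
        return cls(**data)


@dataclass(frozen=True)
class GroundTruth:
    """Per-phantom ground truth: centroids, boxes and the analytic angle.

    ``centroids`` are ordered superior-to-inferior sub-pixel ``(row, col)``
    positions; ``boxes`` are the matching ``(top, left, height, width)``
    integer bounding boxes; ``phi_true`` is the closed-form tangent angle of
    the centerline between the first and last centroid, in degrees.
    """

    centroids: tuple[tuple[float, float], ...]
    boxes: tuple[tuple[int, int, int, int], ...]
    phi_true: float


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _centerline_funcs(spec: PhantomSpec):
    coeffs = np.asarray(spec.centerline_coeffs, dtype=np.float64)
    dcoeffs = npoly.polyder(coeffs) if coeffs.size > 1 else np.zeros(1)
    base_col = (spec.image_shape[1] - 1) / 2.0

    def col_of(row):
        return base_col + npoly.polyval(row, coeffs)

    def slope_of(row):
        return npoly.polyval(row, dcoeffs)

    return col_of, slope_of


def _centroid_rows(spec: PhantomSpec) -> np.ndarray:
    """Row coordinates of the vertebra centers, spaced along the arc."""
    _, slope_of = _centerline_funcs(spec)
    h = spec.vertebra_size[0]
    span_est = (spec.n_vertebrae - 1) * spec.spacing
    r0 = max(h / 2.0 + 1.0, (spec.image_shape[0] - span_est) / 2.0)
    rows = [r0]
    for _ in range(spec.n_vertebrae - 1):
        r = rows[-1]
        dr = spec.spacing / np.hypot(1.0, slope_of(r))
        dr = spec.spacing / np.hypot(1.0, slope_of(r + dr / 2.0))  # midpoint refinement
        rows.append(r + dr)
    return np.asarray(rows)


def _superellipse_mask(shape, center, size, exponent: float = 4.0) -> np.ndarray:
    """Boolean rounded-rectangle (superellipse) blob mask."""
    h, w = size
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    return (np.abs(rr / (h / 2.0)) ** exponent + np.abs(cc / (w / 2.0)) ** exponent) <= 1.0


def ground_truth_for(spec: PhantomSpec) -> GroundTruth:
    """Analytic ground truth of a phantom spec (no rendering needed)."""
    col_of, slope_of = _centerline_funcs(spec)
    rows = _centroid_rows(spec)
    cols = col_of(rows)
    h, w = spec.vertebra_size
    centroids = tuple((float(r), float(c)) for r, c in zip(rows, cols))
    boxes = []
    for r, c in centroids:
        top = int(round(r - h / 2.0))
        left = int(round(c - w / 2.0))
        if top < 0 or left < 0 or top + h > spec.image_shape[0] or left + w > spec.image_shape[1]:
            raise PhantomSpecError(
                f"vertebra at ({r:.1f}, {c:.1f}) exits the {spec.image_shape} image"
            )
        boxes.append((top, left, h, w))
    phi = abs(np.degrees(np.arctan(slope_of(rows[-1])) - np.arctan(slope_of(rows[0]))))
    return GroundTruth(centroids=centroids, boxes=tuple(boxes), phi_true=float(phi))


def generate_spine_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a phantom image and its ground truth.

    Deterministic for a fixed ``spec.seed``: the same spec always yields a
    bit-identical image.  Blob edges are softened with a small Gaussian blur
    before additive Gaussian noise (clipped to [0, 1]) is applied.
    """
    truth = ground_truth_for(spec)
    image = np.full(spec.image_shape, spec.bg_intensity, dtype=np.float64)
    for r, c in truth.centroids:
        blob = _superellipse_mask(spec.image_shape, (r, c), spec.vertebra_size)
        image[blob] = spec.fg_intensity
    image = gaussian_filter(image, sigma=0.8)
    rng = np.random.default_rng(spec.seed)
    image = image + rng.normal(0.0, spec.noise_sd, size=spec.image_shape)
    return np.clip(image, 0.0, 1.0), truth


def truth_masks(spec: PhantomSpec, truth: GroundTruth) -> list[np.ndarray]:
    """Noise-free binary blob masks, one full-image mask per vertebra."""
    return [
        _superellipse_mask(spec.image_shape, c, spec.vertebra_size)
        for c in truth.centroids
    ]


def spec_for_angle(
    angle_deg: float,
    seed: int = 0,
    **overrides,
) -> PhantomSpec:
    """Phantom spec whose centerline has a prescribed terminal tangent angle.

    Uses a quadratic centerline with its vertex at mid-span, so the two
    terminal tangents are symmetric and their angle is ``2*arctan(a*L)`` for
    half-span ``L``; ``a`` is solved from the requested angle.  The exact
    ``phi_true`` (from the realized centroid rows) may differ from the
    nominal angle by a small arc-length correction; truth is always taken
    from :func:`ground_truth_for`.
    """
    base = PhantomSpec(seed=seed, **overrides)
    span = (base.n_vertebrae - 1) * base.spacing
    if angle_deg == 0:
        coeffs = (0.0,)
    else:
        a = np.tan(np.radians(angle_deg) / 2.0) / span
        span_est = (base.n_vertebrae - 1) * base.spacing
        r0 = max(base.vertebra_size[0] / 2.0 + 1.0, (base.image_shape[0] - span_est) / 2.0)
        rc = r0 + span / 2.0
        # a*(r - rc)^2 expanded in ascending powers of r
        coeffs = (float(a * rc * rc), float(-2.0 * a * rc), float(a))
    return dataclasses.replace(base, centerline_coeffs=coeffs, seed=seed)


# ---------------------------------------------------------------------------
# Training patches
# ---------------------------------------------------------------------------


def box_iou(a, b) -> float:
    """Intersection-over-union of two half-open ``(top, left, h, w)`` boxes."""
    at, al, ah, aw = a
    bt, bl, bh, bw = b
    inter_h = min(at + ah, bt + bh) - max(at, bt)
    inter_w = min(al + aw, bl + bw) - max(al, bl)
    if inter_h <= 0 or inter_w <= 0:
        return 0.0
    inter = inter_h * inter_w
    return inter / (ah * aw + bh * bw - inter)


def _crop_resized(image: np.ndarray, box, window) -> np.ndarray:
    top, left, h, w = box
    patch = image[top : top + h, left : left + w]
    if patch.shape != tuple(window):
        patch = resize(patch, window, order=1, anti_aliasing=False)
    return patch


def generate_training_patches(
    spec: PhantomSpec,
    n_pos: int,
    n_neg: int,
    window: tuple[int, int] | None = None,
    jitter: int = 2,
    neg_max_iou: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled window-sized patches cropped from one phantom.

    Positives crop the ground-truth vertebra boxes with uniform +-``jitter``
    px translation (cycling through vertebrae, sampling with replacement
    when ``n_pos`` exceeds the number of distinct crops); negatives are
    background crops overlapping every truth box with IoU below
    ``neg_max_iou``, drawn from a mixture of uniform positions and
    near-miss positions just off a vertebra (the windows a sliding scan
    must learn to reject).  All patches are bilinearly resized to
    ``window`` (default: the vertebra size).  Deterministic for a fixed
    ``spec.seed``.

    Returns ``(patches, labels)`` with labels 1 for vertebra, 0 for
    background.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    image, truth = generate_spine_phantom(spec)
    if window is None:
        window = spec.vertebra_size
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919]))
    rows, cols = image.shape
    patches, labels = [], []

    for i in range(n_pos):
        top, left, h, w = truth.boxes[i % len(truth.boxes)]
        dt = int(rng.integers(-jitter, jitter + 1))
        dl = int(rng.integers(-jitter, jitter + 1))
        top = int(np.clip(top + dt, 0, rows - h))
        left = int(np.clip(left + dl, 0, cols - w))
        patches.append(_crop_resized(image, (top, left, h, w), window))
        labels.append(1)

    wh, ww = window
    attempts = 0
    n_placed = 0
    while n_placed < n_neg:
        attempts += 1
        if attempts > 200 * n_neg:
            raise PhantomSpecError("could not place enough background crops")
        top, left = _propose_negative(rng, truth.boxes, (rows, cols), (wh, ww))
        box = (top, left, wh, ww)
        if max(box_iou(box, tb) for tb in truth.boxes) < neg_max_iou:
            patches.append(image[top : top + wh, left : left + ww].copy())
            labels.append(0)
            n_placed += 1

    return np.stack(patches), np.asarray(labels, dtype=np.int64)


def _propose_negative(rng, boxes, image_shape, window):
    """Candidate top-left for a negative crop: uniform or near a vertebra."""
    rows, cols = image_shape
    wh, ww = window
    if rng.random() < 0.4:
        return (
            int(rng.integers(0, rows - wh + 1)),
            int(rng.integers(0, cols - ww + 1)),
        )
    bt, bl, bh, bw = boxes[int(rng.integers(len(boxes)))]
    if rng.random() < 0.7:  # vertical near-miss (between vertebrae)
        dr = int(rng.integers(wh // 2, 3 * wh // 2 + 1))
        dr *= 1 if rng.random() < 0.5 else -1
        dc = int(rng.integers(-(ww // 2), ww // 2 + 1))
    else:  # lateral near-miss
        dr = int(rng.integers(-(wh // 4), wh // 4 + 1))
        dc = int(rng.integers(ww // 2, ww + 1))
        dc *= 1 if rng.random() < 0.5 else -1
    return (
        int(np.clip(bt + dr, 0, rows - wh)),
        int(np.clip(bl + dc, 0, cols - ww)),
    )


def make_background_sampler(specs, window, neg_max_iou: float = 0.2):
    """Callable ``(n, rng) -> patches`` drawing fresh background crops.

    Used to replenish the cascade's negative pool during bootstrapped stage
    training.  Half of the proposals are uniform over the image; the other
    half are placed just off a vertebra (still below ``neg_max_iou`` overlap)
    so later stages see the hard near-miss windows a sliding scan produces.
    """
    rendered = []
    for spec in specs:
        image, truth = generate_spine_phantom(spec)
        rendered.append((image, truth.boxes))
    wh, ww = window

    def sampler(n: int, rng: np.random.Generator) -> np.ndarray:
        out = []
        attempts = 0
        while len(out) < n and attempts < 200 * n:
            attempts += 1
            image, boxes = rendered[int(rng.integers(len(rendered)))]
            top, left = _propose_negative(rng, boxes, image.shape, (wh, ww))
            if max(box_iou((top, left, wh, ww), b) for b in boxes) < neg_max_iou:
                out.append(image[top : top + wh, left : left + ww].copy())
        return np.stack(out) if out else np.empty((0, wh, ww))

    return sampler


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------


def _box_and_score(det):
    if hasattr(det, "box"):
        return tuple(det.box), float(det.score)
    box, score = det
    return tuple(box), float(score)


def match_detections(detections, truth_boxes, iou_min: float) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detections to truth boxes.

    Detections are visited in descending score order; each claims the
    unmatched truth box of highest IoU, provided it reaches ``iou_min``.
    Returns ``(detection_index, truth_index)`` pairs.
    """
    parsed = [_box_and_score(d) for d in detections]
    order = sorted(range(len(parsed)), key=lambda i: -parsed[i][1])
    taken: set[int] = set()
    pairs = []
    for di in order:
        box, _ = parsed[di]
        best_iou, best_ti = 0.0, None
        for ti, tb in enumerate(truth_boxes):
            if ti in taken:
                continue
            iou = box_iou(box, tb)
            if iou > best_iou:
                best_iou, best_ti = iou, ti
        if best_ti is not None and best_iou >= iou_min:
            taken.add(best_ti)
            pairs.append((di, best_ti))
    return pairs


def detection_recall(detections, truth: GroundTruth, iou_min: float = 0.5) -> float:
    """Fraction of ground-truth boxes matched one-to-one at ``IoU >= iou_min``."""
    if not 0 < iou_min < 1:
        raise ValueError("iou_min must lie in (0, 1)")
    if not truth.boxes:
        raise ValueError("ground truth contains no boxes")
    if not detections:
        return 0.0
    return len(match_detections(detections, truth.boxes, iou_min)) / len(truth.boxes)


def centroid_error(extracted, truth_centroids, spacing_mm: float = 1.0) -> float:
    """Mean Euclidean distance (in mm) between paired centroid lists."""
    extracted = np.asarray(extracted, dtype=np.float64)
    truth_arr = np.asarray(truth_centroids, dtype=np.float64)
    if extracted.shape != truth_arr.shape:
        raise ValueError(
            f"centroid lists differ in shape: {extracted.shape} vs {truth_arr.shape}"
        )
    return float(spacing_mm * np.mean(np.hypot(*(extracted - truth_arr).T)))


def roc_points(scores_pos, scores_neg) -> np.ndarray:
    """ROC curve over all score thresholds, as ``(fpr, tpr)`` rows.

    A sample is called positive when its score is >= the threshold; the
    threshold sweeps all observed scores from high to low, producing a
    monotone curve from (0, 0) to (1, 1).
    """
    pos = np.asarray(scores_pos, dtype=np.float64)
    neg = np.asarray(scores_neg, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    points = [(0.0, 0.0)]
    for th in thresholds:
        tpr = float(np.mean(pos >= th))
        fpr = float(np.mean(neg >= th))
        if (fpr, tpr) != points[-1]:
            points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return np.asarray(points)


# ---------------------------------------------------------------------------
# Ground-truth I/O and phantom-scale pipeline config
# ---------------------------------------------------------------------------


def write_ground_truth(truth: GroundTruth, csv_path: str | Path, meta_path: str | Path) -> None:
    """Write centroids as CSV (index,row,col) plus a YAML sidecar with phi_true."""
    df = pd.DataFrame(
        {
            "index": np.arange(1, len(truth.centroids) + 1),
            "row": [c[0] for c in truth.centroids],
            "col": [c[1] for c in truth.centroids],
        }
    )
    df.to_csv(csv_path, index=False)
    boxes = [list(b) for b in truth.boxes]
    Path(meta_path).write_text(
        yaml.safe_dump({"phi_true": truth.phi_true, "boxes": boxes}, sort_keys=False)
    )


def read_ground_truth(csv_path: str | Path, meta_path: str | Path) -> GroundTruth:
    df = pd.read_csv(csv_path)
    meta = yaml.safe_load(Path(meta_path).read_text())
    centroids = tuple((float(r), float(c)) for r, c in zip(df["row"], df["col"]))
    boxes = tuple(tuple(int(v) for v in b) for b in meta["boxes"])
    return GroundTruth(centroids=centroids, boxes=boxes, phi_true=float(meta["phi_true"]))


def phantom_pipeline_config() -> PipelineConfig:
    """Pipeline configuration scaled to the phantom study.

    The detector window matches the phantom vertebra size (24x20 px) and the
    scan uses a single scale with a 4 px stride, since phantom vertebrae are
    rendered at a fixed size; all other stages keep their defaults.
    """
    return PipelineConfig(
        features=FeatureConfig(window=(24, 20)),
        detector=DetectorConfig(
            n_stages=3, max_weak_learners=25, stride=4, scales=(1.0,)
        ),
    )
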