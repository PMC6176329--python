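"""Cascade gentle-AdaBoost vertebra detector.

A detector is an ordered conjunction of boosted *stages*.  Each stage is a
gentle-AdaBoost ensemble of depth-1 decision stumps over the fused
Haar/LBP/HOG feature vector: sample weights start at ``1/(2m)`` for the
``m`` negatives and ``1/(2l)`` for the ``l`` positives, each round picks the
stump minimizing the weighted misclassification error, and weights of
correctly classified samples are multiplied by ``beta = eps/(1-eps)`` before
renormalization.  The stage score is the additive margin
``sum_t alpha_t h_t(x)`` with ``alpha_t = log(1/beta_t)``; its threshold
starts at half the alpha sum and is then lowered to the largest cut meeting
the stage's true-positive-rate target.

Stages are trained sequentially on bootstrapped negatives: stage ``k+1``
sees only the false positives of the cascade so far (optionally replenished
with fresh background crops), so early stages stay cheap and later stages
concentrate on hard negatives.  A scanned sub-window is accepted only if
every stage accepts it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize, rescale

from .config import DetectorConfig, FeatureConfig
from .features import FeatureExtractor, Normalizer

EPS_CLAMP = 1e-10

MODEL_FORMAT = "spinecurve-cascade"
MODEL_VERSION = 1


@dataclass
class Stump:
    """Depth-1 decision stump on one fused feature.

    Predicts class 1 when ``x <= threshold`` (polarity +1) or when
    ``x > threshold`` (polarity -1).  ``error`` is the weighted
    misclassification error at selection time and ``alpha = log(1/beta)``
    its ensemble coefficient.
    """

    feature: int
    threshold: float
    polarity: int
    error: float
    alpha: float = 0.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        x = X[:, self.feature]
        if self.polarity >= 0:
            return (x <= self.threshold).astype(np.float64)
        return (x > self.threshold).astype(np.float64)


@dataclass
class StageClassifier:
    """One boosted stage: stumps, their alphas, and the adjusted threshold."""

    stumps: list[Stump]
    threshold: float
    tpr: float
    fpr: float
    met_targets: bool

    def scores(self, X: np.ndarray) -> np.ndarray:
        s = np.zeros(X.shape[0])
        for stump in self.stumps:
            s += stump.alpha * stump.predict(X)
        return s

    def decide(self, X: np.ndarray) -> np.ndarray:
        return self.scores(X) >= self.threshold

    @property
    def alpha_sum(self) -> float:
        return sum(s.alpha for s in self.stumps)


@dataclass
class Detection:
    """A scored, sequentially numbered bounding box in image coordinates."""

    number: int
    top: int
    left: int
    height: int
    width: int
    score: float

    @property
    def box(self) -> tuple[int, int, int, int]:
        return (self.top, self.left, self.height, self.width)


@dataclass
class CascadeModel:
    """Trained cascade: stages plus the feature config and normalization."""

    feature_config: FeatureConfig
    normalizer: Normalizer
    stages: list[StageClassifier]
    report: list[dict] = field(default_factory=list)

    @property
    def window(self) -> tuple[int, int]:
        return tuple(self.feature_config.window)

    def evaluate(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cascade decision on normalized feature rows.

        Returns ``(accepted, margins)`` where the margin is the score minus
        threshold of the last stage evaluated for that row (the failing
        stage for rejections, the final stage for acceptances).
        """
        n = X.shape[0]
        accepted = np.ones(n, dtype=bool)
        margins = np.zeros(n)
        active = np.arange(n)
        for stage in self.stages:
            if active.size == 0:
                break
            m = stage.scores(X[active]) - stage.threshold
            margins[active] = m
            passed = m >= 0
            accepted[active[~passed]] = False
            active = active[passed]
        return accepted, margins


def init_weights(labels: np.ndarray) -> np.ndarray:
    """Initial sample weights: ``1/(2m)`` per negative, ``1/(2l)`` per positive."""
    y = np.asarray(labels)
    m = int(np.sum(y == 0))
    l = int(np.sum(y == 1))
    if m < 1 or l < 1:
        raise ValueError("both classes must be present")
    w = np.where(y == 1, 1.0 / (2 * l), 1.0 / (2 * m))
    return w


def train_weak_learner(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    order: np.ndarray | None = None,
) -> Stump:
    """Exhaustive-search decision stump minimizing the weighted error.

    Every midpoint between consecutive distinct sorted values of every
    feature is tried with both polarities; ties are broken by lowest
    feature index, then lowest threshold, then polarity +1.  ``order`` may
    carry a precomputed per-column argsort of ``X`` to amortize sorting
    across boosting rounds.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    n, n_feat = X.shape
    if order is None:
        order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    if np.all(Xs[0] == Xs[-1]):
        raise ValueError("all features are constant")
    ws = w[order]
    ys = y[order]
    cum_p = np.cumsum(ws * ys, axis=0)
    cum_n = np.cumsum(ws * (1.0 - ys), axis=0)
    W_p = cum_p[-1]
    W_n = cum_n[-1]
    # Split after sorted position i: polarity +1 predicts 1 on the left.
    err_pos = cum_n + (W_p - cum_p)
    err_neg = cum_p + (W_n - cum_n)
    valid = np.ones((n, n_feat), dtype=bool)
    valid[:-1] = Xs[1:] > Xs[:-1]
    err_pos = np.where(valid, err_pos, np.inf)
    err_neg = np.where(valid, err_neg, np.inf)
    # Order ties as (feature, split, polarity +1 first): argmin of the
    # flattened (feature, split, polarity) array returns the first minimum.
    stacked = np.stack([err_pos.T, err_neg.T], axis=-1)  # (feat, split, 2)
    flat = int(np.argmin(stacked))
    j, i, pol_idx = np.unravel_index(flat, stacked.shape)
    polarity = 1 if pol_idx == 0 else -1
    if i == n - 1:
        threshold = float(Xs[i, j])
    else:
        threshold = float((Xs[i, j] + Xs[i + 1, j]) / 2.0)
        if threshold >= Xs[i + 1, j]:  # rounding collapse guard
            threshold = float(Xs[i, j])
    return Stump(
        feature=int(j),
        threshold=threshold,
        polarity=polarity,
        error=float(stacked[j, i, pol_idx]),
    )


def update_weights(
    weights: np.ndarray, stump: Stump, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Gentle-AdaBoost weight update: correct samples shrink by ``beta``."""
    eps = np.clip(stump.error, EPS_CLAMP, 0.5 - EPS_CLAMP)
    beta = eps / (1.0 - eps)
    e = (stump.predict(X) != np.asarray(y, dtype=np.float64)).astype(np.float64)
    w = np.asarray(weights, dtype=np.float64) * beta ** (1.0 - e)
    return w / w.sum()


def _adjusted_threshold(scores_pos: np.ndarray, tpr_target: float) -> float:
    """Largest score cut keeping at least ``tpr_target`` of positives."""
    sp = np.sort(scores_pos)
    l = sp.size
    k = int(np.floor((1.0 - tpr_target) * l))
    k = min(k, l - 1)
    return float(sp[k])


def train_stage(
    X: np.ndarray,
    y: np.ndarray,
    tpr_target: float = 0.9,
    fpr_target: float = 0.03,
    max_learners: int = 40,
    min_learners: int = 1,
) -> StageClassifier:
    """Boost stumps until the TPR/FPR targets are met (or ``max_learners``).

    After each round the stage threshold is set to the largest additive-score
    cut achieving the TPR target on the training positives, and the stage
    stops as soon as at least ``min_learners`` rounds have run and the
    resulting training FPR drops to the target.  (A floor above 1 keeps the
    stage margin graded even on easy data, which the scan's non-maximum
    suppression relies on to rank overlapping windows.)  If the targets are
    unreachable, the best stage is returned with ``met_targets=False`` and a
    warning.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    w = init_weights(y)
    order = np.argsort(X, axis=0, kind="stable")
    stumps: list[Stump] = []
    scores = np.zeros(X.shape[0])
    pos = y == 1
    threshold = 0.0
    tpr = fpr = 0.0
    for t in range(max_learners):
        w = w / w.sum()
        stump = train_weak_learner(X, y, w, order=order)
        eps = float(np.clip(stump.error, EPS_CLAMP, 0.5 - EPS_CLAMP))
        beta = eps / (1.0 - eps)
        stump.alpha = float(np.log(1.0 / beta))
        w = update_weights(w, stump, X, y)
        stumps.append(stump)
        scores += stump.alpha * stump.predict(X)
        threshold = _adjusted_threshold(scores[pos], tpr_target)
        tpr = float(np.mean(scores[pos] >= threshold))
        fpr = float(np.mean(scores[~pos] >= threshold))
        if t + 1 >= min_learners and tpr >= tpr_target and fpr <= fpr_target:
            return StageClassifier(stumps, threshold, tpr, fpr, met_targets=True)
    warnings.warn(
        f"stage targets (TPR>={tpr_target}, FPR<={fpr_target}) not reached "
        f"after {max_learners} learners: TPR={tpr:.3f}, FPR={fpr:.3f}",
        stacklevel=2,
    )
    return StageClassifier(stumps, threshold, tpr, fpr, met_targets=False)


def train_cascade(
    pos_patches,
    neg_patches,
    feature_config: FeatureConfig,
    detector_config: DetectorConfig | None = None,
    neg_sampler=None,
    rng: np.random.Generator | None = None,
) -> CascadeModel:
    """Train the full cascade from labeled window-sized patches.

    ``neg_sampler(n, rng) -> patches`` may be supplied to replenish the
    negative pool with fresh background crops once the cascade rejects the
    current ones; without it, training stops early when no false positives
    remain.  Feature normalization statistics are fitted on the initial
    training set and stored with the model.
    """
    cfg = detector_config or DetectorConfig()
    rng = rng or np.random.default_rng(0)
    extractor = FeatureExtractor(feature_config)
    pos_list = [np.asarray(p, dtype=np.float64) for p in pos_patches]
    neg_list = [np.asarray(p, dtype=np.float64) for p in neg_patches]
    if not pos_list or not neg_list:
        raise ValueError("positive and negative patch sets must be non-empty")
    Xp_raw = extractor.extract_many(pos_list)
    Xn_raw = extractor.extract_many(neg_list)
    normalizer = Normalizer().fit(np.vstack([Xp_raw, Xn_raw]))
    Xp = normalizer.transform(Xp_raw)
    Xn = normalizer.transform(Xn_raw)
    n_neg_target = Xn.shape[0]

    model = CascadeModel(feature_config, normalizer, stages=[])
    for k in range(cfg.n_stages):
        if Xn.shape[0] == 0:
            Xn = _replenish(model, extractor, neg_sampler, n_neg_target, rng)
            if Xn.shape[0] == 0:
                break  # no false positives remain anywhere we can sample
        X = np.vstack([Xp, Xn])
        y = np.concatenate([np.ones(Xp.shape[0]), np.zeros(Xn.shape[0])])
        stage = train_stage(
            X,
            y,
            cfg.tpr_target,
            cfg.fpr_target,
            cfg.max_weak_learners,
            cfg.min_weak_learners,
        )
        model.stages.append(stage)
        model.report.append(
            {
                "stage": k + 1,
                "n_learners": len(stage.stumps),
                "tpr": stage.tpr,
                "fpr": stage.fpr,
                "met_targets": stage.met_targets,
                "n_pos": int(Xp.shape[0]),
                "n_neg": int(Xn.shape[0]),
            }
        )
        # Pass-through semantics: only accepted positives continue; the
        # accepted negatives are the false positives that seed stage k+1.
        Xp = Xp[stage.decide(Xp)]
        if Xp.shape[0] < 2:
            raise ValueError(f"positives exhausted after stage {k + 1}")
        Xn = Xn[stage.decide(Xn)]
        if Xn.shape[0] < n_neg_target:
            extra = _replenish(
                model, extractor, neg_sampler, n_neg_target - Xn.shape[0], rng
            )
            if extra.shape[0]:
                Xn = np.vstack([Xn, extra])
        if Xn.shape[0] == 0 and neg_sampler is None:
            break
    return model


def _replenish(model, extractor, neg_sampler, n_wanted, rng, max_rounds: int = 15):
    """Draw background crops and keep those the cascade-so-far accepts."""
    if neg_sampler is None or n_wanted <= 0:
        return np.empty((0, extractor.n_features))
    kept = []
    total = 0
    for _ in range(max_rounds):
        batch = neg_sampler(max(n_wanted * 2, 32), rng)
        if batch.shape[0] == 0:
            break
        Xb = model.normalizer.transform(extractor.extract_many(batch))
        accepted, _ = model.evaluate(Xb)
        if accepted.any():
            kept.append(Xb[accepted])
            total += int(accepted.sum())
        if total >= n_wanted:
            break
    if not kept:
        return np.empty((0, extractor.n_features))
    return np.vstack(kept)[:n_wanted]


def classify_window(model: CascadeModel, patch: np.ndarray) -> tuple[bool, float]:
    """Run one patch through the cascade; returns ``(accepted, margin)``.

    The patch is resized to the model window if needed; the margin is the
    score-minus-threshold of the last stage evaluated.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape != model.window:
        patch = resize(patch, model.window, order=1, anti_aliasing=False)
    extractor = FeatureExtractor(model.feature_config)
    x = model.normalizer.transform(extractor.extract(patch)[None, :])
    accepted, margins = model.evaluate(x)
    return bool(accepted[0]), float(margins[0])


def _merge_windows(
    boxes: list[tuple[int, int, int, int]],
    scores: list[float],
    strides: list[float],
    iou_max: float,
    link_factor: float = 2.2,
) -> tuple[list[tuple[int, int, int, int]], list[float]]:
    """Group accepted scan windows and average each group into one box.

    A sliding scan accepts a contiguous run of grid positions around each
    object, so two windows are linked when their centers are within
    ``link_factor`` effective strides in both axes (bridging single-hole
    gaps in the run) or when they overlap with IoU above ``iou_max``
    (duplicates across pyramid scales).  Connected groups are averaged —
    which centers the surviving box on the object even when cascade margins
    are tied — and scored with their best member's margin.
    """
    from .phantom import box_iou  # local import to avoid a cycle at import time

    n = len(boxes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    centers = [(t + h / 2.0, l + w / 2.0) for t, l, h, w in boxes]
    for i in range(n):
        for j in range(i + 1, n):
            reach = link_factor * max(strides[i], strides[j])
            close = (
                abs(centers[i][0] - centers[j][0]) <= reach
                and abs(centers[i][1] - centers[j][1]) <= reach
            )
            if close or box_iou(boxes[i], boxes[j]) > iou_max:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged_boxes, merged_scores = [], []
    for members in groups.values():
        arr = np.asarray([boxes[i] for i in members], dtype=np.float64)
        merged_boxes.append(tuple(int(round(v)) for v in arr.mean(axis=0)))
        merged_scores.append(max(scores[i] for i in members))
    return merged_boxes, merged_scores


def detect(
    model: CascadeModel,
    image: np.ndarray,
    detector_config: DetectorConfig | None = None,
) -> list[Detection]:
    """Sliding-window scan with an image pyramid, NMS, and raster numbering.

    The window slides left-to-right, top-to-bottom at the configured stride
    over each pyramid scale (the image shrinks by ``pyramid_scale`` per
    level so larger vertebrae map onto the fixed window).  Accepted windows
    are merged by non-maximum suppression on descending score; survivors
    are numbered 1..K by raster order of their top-left corner.
    """
    cfg = detector_config or DetectorConfig()
    image = np.asarray(image, dtype=np.float64)
    wr, wc = model.window
    if image.shape[0] < wr or image.shape[1] < wc:
        raise ValueError(f"image {image.shape} smaller than window {model.window}")
    if cfg.scales is not None:
        scales = list(cfg.scales)
    else:
        scales, s = [], 1.0
        while image.shape[0] * s >= wr and image.shape[1] * s >= wc:
            scales.append(s)
            s /= cfg.pyramid_scale

    extractor = FeatureExtractor(model.feature_config)
    boxes: list[tuple[int, int, int, int]] = []
    scores: list[float] = []
    strides: list[float] = []
    for s in scales:
        if s == 1.0:
            scaled = image
        else:
            scaled = rescale(image, s, order=1, anti_aliasing=s < 1.0)
        if scaled.shape[0] < wr or scaled.shape[1] < wc:
            continue
        feats, positions = [], []
        for top in range(0, scaled.shape[0] - wr + 1, cfg.stride):
            for left in range(0, scaled.shape[1] - wc + 1, cfg.stride):
                feats.append(extractor.extract(scaled[top : top + wr, left : left + wc]))
                positions.append((top, left))
        if not feats:
            continue
        X = model.normalizer.transform(np.stack(feats))
        accepted, margins = model.evaluate(X)
        inv = 1.0 / s
        for (top, left), ok, margin in zip(positions, accepted, margins):
            if ok:
                boxes.append(
                    (
                        int(round(top * inv)),
                        int(round(left * inv)),
                        int(round(wr * inv)),
                        int(round(wc * inv)),
                    )
                )
                scores.append(float(margin))
                strides.append(cfg.stride * inv)
    merged_boxes, merged_scores = _merge_windows(boxes, scores, strides, cfg.nms_iou)
    order = sorted(range(len(merged_boxes)), key=lambda i: merged_boxes[i][:2])
    return [
        Detection(
            number=n + 1,
            top=merged_boxes[i][0],
            left=merged_boxes[i][1],
            height=merged_boxes[i][2],
            width=merged_boxes[i][3],
            score=merged_scores[i],
        )
        for n, i in enumerate(order)
    ]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: CascadeModel, path: str | Path) -> None:
    """Write the cascade as a versioned JSON document (lossless round trip)."""
    import dataclasses as dc

    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "feature_config": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in dc.asdict(model.feature_config).items()
        },
        "normalization": model.normalizer.to_dict(),
        "stages": [
            {
                "threshold": st.threshold,
                "tpr": st.tpr,
                "fpr": st.fpr,
                "met_targets": st.met_targets,
                "stumps": [
                    {
                        "feature": s.feature,
                        "threshold": s.threshold,
                        "polarity": s.polarity,
                        "error": s.error,
                        "alpha": s.alpha,
                    }
                    for s in st.stumps
                ],
            }
            for st in model.stages
        ],
        "report": model.report,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> CascadeModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != MODEL_FORMAT:
        raise ValueError(f"not a cascade model file: {path}")
    if doc.get("version") != MODEL_VERSION:
        raise ValueError(f"unsupported model version {doc.get('version')}")
    fc_data = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in doc["feature_config"].items()
    }
    feature_config = FeatureConfig(**fc_data)
    normalizer = Normalizer.from_dict(doc["normalization"])
    stages = [
        StageClassifier(
            stumps=[Stump(**s) for s in st["stumps"]],
            threshold=st["threshold"],
            tpr=st["tpr"],
            fpr=st["fpr"],
            met_targets=st["met_targets"],
        )
        for st in doc["stages"]
    ]
    return CascadeModel(feature_config, normalizer, stages, doc.get("report", []))
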