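"""Accuracy surfaces, confusion-derived metrics, and classification maps.

Four accuracy definitions are used for pixel-level classifiers:

* per-pixel accuracy — correct pixels over all valid pixels, pooled;
* per-image accuracy — the unweighted mean (and SD) over images of each
  image's own per-pixel accuracy;
* majority-pixel-per-image — plurality vote of the pixels in an image; a
  tie for the top count makes the image count as incorrect;
* per-image-spectrum accuracy — fraction of correctly classified mean
  image spectra.

Classification maps are rendered at the binned cube resolution with
masked/specular pixels marked distinctly, optionally cleaned with a
single-pass 4-neighbor mode noise filter, and paired with false-RGB
composites of selected bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .raw import ImageCube, MASK_SATURATED, MASK_VALID


def per_pixel_accuracy(pred: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Percentage of valid pixels classified correctly, pooled over all
    supplied pixels.  ``mask`` (optional boolean) selects the valid pixels;
    masked pixels enter neither numerator nor denominator."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != pred.shape:
            raise ValueError("mask shape differs")
        pred, truth = pred[mask], truth[mask]
    if pred.size == 0:
        raise ValueError("no valid pixels")
    return 100.0 * float(np.mean(pred == truth))


def per_image_accuracy(per_image_preds: list, per_image_truths: list) -> tuple[float, float, int]:
    """Unweighted mean and SD over images of each image's per-pixel accuracy.

    Images with zero valid pixels are excluded; the number of excluded
    images is returned as the third element.
    """
    accs = []
    excluded = 0
    for pred, truth in zip(per_image_preds, per_image_truths):
        pred = np.asarray(pred)
        t = np.broadcast_to(np.asarray(truth), pred.shape)
        if pred.size == 0:
            excluded += 1
            continue
        accs.append(100.0 * float(np.mean(pred == t)))
    if not accs:
        raise ValueError("no images with valid pixels")
    return float(np.mean(accs)), float(np.std(accs)), excluded


def majority_per_image(pixel_preds: np.ndarray, truth_class) -> tuple[bool, bool]:
    """Plurality decision for one image.

    Returns ``(correct, tied)``.  The image is correct only if a single
    class holds the top vote count and it equals the truth; any tie for the
    top count counts the image as incorrectly classified (and is also
    reported so tied images can be tallied separately).
    """
    pixel_preds = np.asarray(pixel_preds)
    if pixel_preds.size == 0:
        raise ValueError("image has no valid pixels")
    vals, counts = np.unique(pixel_preds, return_counts=True)
    winners = vals[counts == counts.max()]
    if len(winners) > 1:
        return False, True
    return bool(winners[0] == truth_class), False


def majority_accuracy(per_image_preds: list, truths: list) -> tuple[float, int, int]:
    """Majority-pixel-per-image accuracy (%) over a set of images, plus the
    count of tied images and of excluded (zero-valid-pixel) images."""
    correct = 0
    ties = 0
    excluded = 0
    n = 0
    for pred, truth in zip(per_image_preds, truths):
        pred = np.asarray(pred)
        if pred.size == 0:
            excluded += 1
            continue
        ok, tied = majority_per_image(pred, truth)
        correct += ok
        ties += tied
        n += 1
    if n == 0:
        raise ValueError("no images with valid pixels")
    return 100.0 * correct / n, ties, excluded


@dataclass
class BinaryMetrics:
    """2x2 confusion-derived rates (%) with the designated positive class.
    A rate whose denominator is empty is undefined (None), not 0."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    tp: int
    fp: int
    tn: int
    fn: int


def confusion_and_metrics(preds, truths, classes, positive_class=None):
    """Confusion matrix (rows = truth, in the order of ``classes``) and,
    when ``positive_class`` is given, the standard 2x2 metrics for
    detecting that class against all others."""
    preds = np.asarray(preds)
    truths = np.asarray(truths)
    classes = list(classes)
    cm = _sk_confusion(truths, preds, labels=classes)
    metrics = None
    if positive_class is not None:
        pos_t = truths == positive_class
        pos_p = preds == positive_class
        tp = int(np.sum(pos_t & pos_p))
        fn = int(np.sum(pos_t & ~pos_p))
        fp = int(np.sum(~pos_t & pos_p))
        tn = int(np.sum(~pos_t & ~pos_p))

        def rate(num, den):
            return 100.0 * num / den if den > 0 else None

        metrics = BinaryMetrics(
            sensitivity=rate(tp, tp + fn),
            specificity=rate(tn, tn + fp),
            ppv=rate(tp, tp + fp),
            npv=rate(tn, tn + fn),
            tp=tp,
            fp=fp,
            tn=tn,
            fn=fn,
        )
    return cm, metrics


# ---------------------------------------------------------------------------
# classification maps


@dataclass
class ClassificationMap:
    """Class labels at binned-cube resolution; masked (specular etc.)
    pixels carry no class and are rendered white."""

    labels: np.ndarray  # (h, w) int, -1 where masked
    mask: np.ndarray  # (h, w) uint8 mask codes
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.labels.shape != self.mask.shape:
            raise ValueError("labels and mask must share dimensions")


def mode_noise_filter(cmap: ClassificationMap) -> ClassificationMap:
    """Single-pass 4-neighbor mode filter for isolated noise pixels.

    A pixel is replaced only when *all* of its available valid 4-neighbors
    hold a different class than the pixel itself; the replacement is the
    mode of those neighbors, ties resolved to the lowest class index.
    Border pixels use their in-bounds neighbors; masked neighbors are
    ignored (a pixel with no valid neighbor is left unchanged).
    """
    h, w = cmap.labels.shape
    if h < 3 or w < 3:
        raise ValueError("map must be at least 3x3")
    labels = cmap.labels
    valid = cmap.mask == MASK_VALID
    out = labels.copy()
    for r in range(h):
        for c in range(w):
            if not valid[r, c]:
                continue
            neigh = []
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and valid[rr, cc]:
                    neigh.append(labels[rr, cc])
            if not neigh:
                continue
            neigh = np.asarray(neigh)
            if np.all(neigh != labels[r, c]):
                vals, counts = np.unique(neigh, return_counts=True)
                out[r, c] = vals[counts == counts.max()].min()
    return ClassificationMap(out, cmap.mask.copy(), dict(cmap.provenance))


#: default false-RGB assignment: bands 3, 2, 1 to R, G, B (1-based)
FALSE_RGB_DEFAULT = (2, 1, 0)
#: alternative composite: bands 2, 3 and the broadband channel to R, G, B
FALSE_RGB_BROADBAND = (1, 2, 8)


def false_rgb(cube: ImageCube, band_assignment: tuple = FALSE_RGB_DEFAULT) -> np.ndarray:
    """Compose a false-color image from three bands of a cube.

    Each channel is min-max scaled over valid pixels to [0, 1]; masked and
    specular pixels are rendered white.  Returns (h, w, 3) floats.
    """
    for b in band_assignment:
        if not 0 <= b < cube.values.shape[2]:
            raise ValueError(f"invalid band index {b}")
    h, w = cube.values.shape[:2]
    out = np.ones((h, w, 3))
    valid = cube.mask == MASK_VALID
    for ch, b in enumerate(band_assignment):
        plane = cube.values[:, :, b]
        if valid.any():
            lo = plane[valid].min()
            hi = plane[valid].max()
            span = hi - lo if hi > lo else 1.0
            out[:, :, ch] = np.where(valid, (plane - lo) / span, 1.0)
    return out


def map_from_predictions(
    cube: ImageCube, flat_labels: np.ndarray, provenance: dict | None = None
) -> ClassificationMap:
    """Assemble a ClassificationMap from per-valid-pixel predictions given
    in row-major order of the cube's valid pixels."""
    labels = np.full(cube.mask.shape, -1, dtype=int)
    labels[cube.mask == MASK_VALID] = flat_labels
    return ClassificationMap(labels, cube.mask.copy(), dict(provenance or {}))


def specular_fraction(cube: ImageCube) -> float:
    """Fraction of pixels masked as saturated/specular (diagnostic)."""
    return float(np.mean(cube.mask == MASK_SATURATED))
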