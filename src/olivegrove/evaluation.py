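"""Detection evaluation: ground-truth masks, point-in-contour matching,
micro-averaged metrics and the capture-level k-fold protocol.

Ground truth is built by dilating the olive-labelled pixels with a circular
kernel (default diameter 11 px) so each canopy becomes a filled contour. A
predicted coordinate inside any contour is a true positive, outside all of
them a false positive; a contour containing no prediction is a false
negative. Several predictions inside one contour all count as true
positives, so TP + FN need not equal the contour count P: recall is TP / P
and precision TP / PP by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from olivegrove.features import LabelledPixel
from olivegrove.marking import disc_kernel

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class DetectionOutcome:
    """Counts and derived metrics for one capture (or an aggregate)."""

    P: int  # ground-truth contours
    PP: int  # predicted positives
    TP: int
    FN: int
    FP: int

    def __post_init__(self) -> None:
        if self.TP + self.FP != self.PP:
            raise ValueError("TP + FP must equal PP")
        if self.FN > self.P:
            raise ValueError("FN cannot exceed P")

    @property
    def recall(self) -> float:
        return self.TP / self.P if self.P else 0.0

    @property
    def precision(self) -> float:
        return self.TP / self.PP if self.PP else 0.0

    @property
    def f1(self) -> float:
        r, p = self.recall, self.precision
        return 2 * r * p / (r + p) if r + p else 0.0

    @property
    def omission_error(self) -> float:
        """1 - recall (not FN/P: multiple hits per contour keep FN/P larger)."""
        return 1.0 - self.recall

    @property
    def estimation_error(self) -> float:
        """Relative error of the detected count: |PP - P| / P."""
        return abs(self.PP - self.P) / self.P if self.P else 0.0


def build_ground_truth(
    olive_pixels: Sequence[LabelledPixel] | np.ndarray,
    shape: tuple[int, int],
    kernel_diameter: float = 11.0,
) -> np.ndarray:
    """Binary canopy mask: olive pixels dilated by a disc of given diameter.

    ``olive_pixels`` is either labelled pixels (non-olive ones are ignored)
    or an (n, 2) array of (x, y) coordinates. Dilation is extensive: every
    input pixel is inside the mask.
    """
    seed = np.zeros(shape, dtype=bool)
    if isinstance(olive_pixels, np.ndarray):
        coords = olive_pixels
        for x, y in coords.reshape(-1, 2):
            seed[int(y), int(x)] = True
    else:
        for p in olive_pixels:
            if p.label == "olive":
                seed[p.y, p.x] = True
    if not seed.any():
        return seed.astype(np.uint8)
    structure = disc_kernel(kernel_diameter).astype(bool)
    return ndimage.binary_dilation(seed, structure=structure).astype(np.uint8)


def match(canopies: np.ndarray, truth: np.ndarray) -> DetectionOutcome:
    """Match predicted centroids against ground-truth contours.

    Contours are the 8-connected components of the truth mask; a predicted
    point belongs to a contour if the pixel containing its rounded
    coordinates does.
    """
    truth = np.asarray(truth)
    labels, n_components = ndimage.label(truth > 0, structure=_EIGHT_CONNECTED)
    points = np.asarray(canopies, dtype=np.float64).reshape(-1, 2)
    h, w = truth.shape
    tp = 0
    hit: set[int] = set()
    for x, y in points:
        col, row = int(round(x)), int(round(y))
        if 0 <= row < h and 0 <= col < w and labels[row, col] > 0:
            tp += 1
            hit.add(int(labels[row, col]))
    pp = len(points)
    return DetectionOutcome(
        P=int(n_components),
        PP=pp,
        TP=tp,
        FN=int(n_components) - len(hit),
        FP=pp - tp,
    )


def aggregate(outcomes: Iterable[DetectionOutcome]) -> DetectionOutcome:
    """Micro-aggregate: sum the counts, then recompute the metrics from sums.

    The aggregate recall is sum(TP)/sum(P) — never the mean of per-capture
    recalls.
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("nothing to aggregate")
    return DetectionOutcome(
        P=sum(o.P for o in outcomes),
        PP=sum(o.PP for o in outcomes),
        TP=sum(o.TP for o in outcomes),
        FN=sum(o.FN for o in outcomes),
        FP=sum(o.FP for o in outcomes),
    )


def kfold_split(
    capture_ids: Sequence[str], folds: int = 5, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Capture-level k-fold partition (never pixel-level).

    Labelled pixels from one capture must stay together in train or test, so
    the split is over capture ids: each id lands in exactly one test fold,
    fold sizes differ by at most one.
    """
    ids = list(capture_ids)
    if not 1 <= folds <= len(ids):
        raise ValueError("fold count must lie in [1, number of captures]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    test_folds = [
        [str(x) for x in chunk] for chunk in np.array_split(np.array(shuffled), folds)
    ]
    splits = []
    for test in test_folds:
        test_set = set(test)
        train = [i for i in ids if i not in test_set]
        splits.append((train, list(test)))
    return splits
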