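"""Olive-canopy probability image.

A binary decision tree is trained on the olive-vs-weed labelled pixels (in
CIELAB). Its hard classification of olive pixels is not reliable, but the
per-leaf class fractions are informative: each leaf's probability is the
number of olive training pixels in the leaf divided by the leaf's total
training pixels. Scoring every vegetation-mask pixel with its leaf
probability yields the probability image consumed by the canopy-marking
stage; pixels outside the mask are exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.tree import DecisionTreeClassifier

from olivegrove.features import LabelledPixel, pixels_to_features, rgb_reflectance_to_cielab

_TILE = 1 << 16


class TreeTrainingError(ValueError):
    pass


@dataclass
class CanopyTree:
    """Fitted decision tree whose leaf probabilities score canopy membership."""

    tree: DecisionTreeClassifier
    seed: int

    @property
    def _olive_index(self) -> int:
        return int(np.nonzero(self.tree.classes_ == "olive")[0][0])

    def olive_probability(self, features: np.ndarray) -> np.ndarray:
        """Per-sample olive-leaf probability (olive fraction of the leaf)."""
        return self.tree.predict_proba(features)[:, self._olive_index]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        joblib.dump(self.tree, path)
        params = {"seed": self.seed, "max_depth": self.tree.get_params()["max_depth"]}
        path.with_suffix(".json").write_text(json.dumps(params, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CanopyTree":
        path = Path(path)
        params = json.loads(path.with_suffix(".json").read_text())
        return cls(tree=joblib.load(path), seed=params["seed"])


def train_canopy_tree(
    pixels: Sequence[LabelledPixel],
    seed: int = 0,
    max_depth: int | None = None,
) -> CanopyTree:
    """Fit the olive-vs-weed tree; deterministic for a fixed seed.

    Depth is unlimited by default: only the leaf probabilities matter
    downstream, not the tree's generalising hard classification.
    """
    labels = [p.label for p in pixels]
    present = set(labels)
    if not present <= {"olive", "weed"}:
        raise TreeTrainingError(
            f"canopy tree accepts only olive/weed pixels, got {sorted(present)}"
        )
    if present != {"olive", "weed"}:
        raise TreeTrainingError("training needs both olive and weed pixels")
    features = pixels_to_features(pixels)
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    tree.fit(features, np.asarray(labels))
    return CanopyTree(tree=tree, seed=seed)


def predict_probability_image(
    red: np.ndarray,
    green: np.ndarray,
    blue: np.ndarray,
    mask: np.ndarray,
    tree: CanopyTree,
) -> np.ndarray:
    """Score masked-in pixels with their olive leaf probability.

    Returns a float32 raster in [0, 1]; pixels outside the vegetation mask
    are exactly 0, so the probability image's support is a subset of the
    mask.
    """
    red = np.asarray(red)
    mask = np.asarray(mask)
    if mask.shape != red.shape:
        raise ValueError("mask and band rasters must share one shape")
    out = np.zeros(red.shape, dtype=np.float32)
    idx = np.nonzero(mask)
    if idx[0].size == 0:
        return out
    lab = rgb_reflectance_to_cielab(
        np.asarray(red)[idx], np.asarray(green)[idx], np.asarray(blue)[idx]
    ).reshape(-1, 3)
    probs = np.empty(lab.shape[0], dtype=np.float32)
    for start in range(0, lab.shape[0], _TILE):
        chunk = lab[start : start + _TILE]
        probs[start : start + chunk.shape[0]] = tree.olive_probability(chunk)
    out[idx] = probs
    return out
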