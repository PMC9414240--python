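"""One-class vegetation classification.

Manual labelling only marks pixels that certainly belong to a class, so a
conventional multi-class classifier would be forced to assign one of the four
classes to every pixel of a capture, producing false positives on roads,
rocks, buildings and the like. Instead, a local-outlier-factor (LOF) novelty
detector is trained on the vegetation labels alone (olive + weed, in CIELAB)
and every capture pixel is scored: inliers form the binary vegetation mask.

The contamination is pinned at its maximum (0.5) so that surviving pixels are
vegetation with high confidence, at the price of discarding some true
vegetation; the neighbour count defaults to 100. Neither choice is critical
for the downstream stages, and both are exposed as parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.neighbors import LocalOutlierFactor

from olivegrove.features import LabelledPixel, pixels_to_features, rgb_reflectance_to_cielab

#: Pixels scored per prediction batch; bounds memory on full rasters.
_TILE = 1 << 16


class VegetationTrainingError(ValueError):
    pass


@dataclass
class VegetationModel:
    """Fitted LOF novelty detector over CIELAB features."""

    lof: LocalOutlierFactor
    n_neighbors: int
    contamination: float
    n_training: int

    def save(self, path: str | Path) -> None:
        """Persist the detector plus a JSON echo of its parameters."""
        path = Path(path)
        joblib.dump(self.lof, path)
        params = {
            "n_neighbors": self.n_neighbors,
            "contamination": self.contamination,
            "n_training": self.n_training,
        }
        path.with_suffix(".json").write_text(json.dumps(params, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "VegetationModel":
        path = Path(path)
        lof = joblib.load(path)
        params = json.loads(path.with_suffix(".json").read_text())
        return cls(lof=lof, **params)


def train_vegetation_model(
    pixels: Sequence[LabelledPixel],
    n_neighbors: int = 100,
    contamination: float = 0.5,
) -> VegetationModel:
    """Fit the one-class vegetation detector on olive/weed labelled pixels."""
    labels = {p.label for p in pixels}
    if not labels <= {"olive", "weed"}:
        raise VegetationTrainingError(
            f"vegetation training accepts only olive/weed pixels, got {sorted(labels)}"
        )
    if len(pixels) <= n_neighbors:
        raise VegetationTrainingError(
            f"need more than n_neighbors={n_neighbors} training pixels, got {len(pixels)}"
        )
    if not 0 < contamination <= 0.5:
        raise VegetationTrainingError("contamination must lie in (0, 0.5]")
    features = pixels_to_features(pixels)
    lof = LocalOutlierFactor(
        n_neighbors=n_neighbors, contamination=contamination, novelty=True
    )
    lof.fit(features)
    return VegetationModel(
        lof=lof,
        n_neighbors=n_neighbors,
        contamination=contamination,
        n_training=len(pixels),
    )


def predict_vegetation_mask(
    red: np.ndarray, green: np.ndarray, blue: np.ndarray, model: VegetationModel
) -> np.ndarray:
    """Score every pixel of a corrected capture; returns a 0/1 uint8 mask.

    The three rasters must share one shape; pixels are converted to CIELAB
    and scored in fixed-size batches.
    """
    red = np.asarray(red)
    if red.shape != np.shape(green) or red.shape != np.shape(blue):
        raise ValueError("band rasters must share one shape")
    lab = rgb_reflectance_to_cielab(
        np.ravel(red), np.ravel(green), np.ravel(blue)
    ).reshape(-1, 3)
    flags = np.empty(lab.shape[0], dtype=np.uint8)
    for start in range(0, lab.shape[0], _TILE):
        chunk = lab[start : start + _TILE]
        flags[start : start + chunk.shape[0]] = (model.lof.predict(chunk) == 1)
    return flags.reshape(red.shape)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write the mask as an 8-bit raster with foreground 255."""
    import tifffile

    tifffile.imwrite(Path(path), (np.asarray(mask, dtype=np.uint8) * 255))


def load_mask(path: str | Path) -> np.ndarray:
    import tifffile

    return (np.asarray(tifffile.imread(Path(path))) > 0).astype(np.uint8)
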