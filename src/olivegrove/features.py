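"""Colour features and labelled-pixel handling.

Only the red, green and blue reflectance bands feed the classifiers; they are
converted to CIELAB so that distances in feature space approximate perceived
colour differences. Reflectance is open-ended above 1 (HDRF), so the
conversion treats the triplet as *linear* RGB under the sRGB primaries and a
D65 white point and never clips the input.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skimage.color import xyz2lab

#: Closed class enumeration for manual labels. There is deliberately no
#: catch-all "other" class: unlabelled pixels are heterogeneous (roads, rocks,
#: buildings, ...) and would smear the class boundaries.
LABEL_CLASSES = ("olive", "ground", "weed", "shadow")

#: Linear-RGB -> XYZ matrix for sRGB primaries, D65 white (rows sum to the
#: D65 white point so equal-grey inputs land on the achromatic axis).
_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)


class LabelParseError(ValueError):
    """Malformed labels file; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class LabelledPixel:
    """One manually labelled pixel: five band reflectances plus its class."""

    capture_id: str
    x: int  # column, 0-based
    y: int  # row, 0-based
    blue: float
    green: float
    red: float
    nir: float
    rededge: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABEL_CLASSES:
            raise ValueError(f"unknown class {self.label!r}")


def rgb_reflectance_to_cielab(
    r: float | np.ndarray, g: float | np.ndarray, b: float | np.ndarray
) -> np.ndarray:
    """Convert linear reflectance triplets to CIELAB.

    Accepts scalars or equally shaped arrays; returns an array with a
    trailing axis of length 3 holding (L*, a*, b*). Inputs above 1 are legal
    (HDRF is unbounded above) and are passed through the Lab transfer
    function unclipped; negative inputs are a domain error.
    """
    r = np.asarray(r, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if np.any(r < 0) or np.any(g < 0) or np.any(b < 0):
        raise ValueError("reflectance must be non-negative")
    rgb = np.stack(np.broadcast_arrays(r, g, b), axis=-1)
    xyz = rgb @ _RGB_TO_XYZ.T
    return xyz2lab(xyz, illuminant="D65", observer="2")


def pixels_to_features(pixels: Sequence[LabelledPixel]) -> np.ndarray:
    """(n, 3) Lab feature matrix from labelled pixels (red/green/blue only)."""
    if not pixels:
        return np.empty((0, 3))
    r = np.array([p.red for p in pixels])
    g = np.array([p.green for p in pixels])
    b = np.array([p.blue for p in pixels])
    return rgb_reflectance_to_cielab(r, g, b)


_HEADER = ["capture_id", "x", "y", "blue", "green", "red", "nir", "rededge", "class"]


def write_labels(pixels: Iterable[LabelledPixel], path: str | Path) -> None:
    """Write labelled pixels as CSV (lossless round trip with read_labels)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for p in pixels:
            writer.writerow(
                [p.capture_id, p.x, p.y,
                 repr(p.blue), repr(p.green), repr(p.red),
                 repr(p.nir), repr(p.rededge), p.label]
            )


def read_labels(path: str | Path) -> list[LabelledPixel]:
    """Read a labels CSV; rejects unknown classes and malformed rows."""
    pixels: list[LabelledPixel] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return []
        if header != _HEADER:
            raise LabelParseError(1, f"unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_HEADER):
                raise LabelParseError(lineno, f"expected {len(_HEADER)} fields, got {len(row)}")
            try:
                pixel = LabelledPixel(
                    capture_id=row[0],
                    x=int(row[1]),
                    y=int(row[2]),
                    blue=float(row[3]),
                    green=float(row[4]),
                    red=float(row[5]),
                    nir=float(row[6]),
                    rededge=float(row[7]),
                    label=row[8],
                )
            except ValueError as exc:
                raise LabelParseError(lineno, str(exc)) from exc
            pixels.append(pixel)
    return pixels
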