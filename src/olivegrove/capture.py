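"""Multispectral capture container and on-disk layout.

A capture is five co-registered single-band rasters (blue, green, red, NIR,
red-edge) plus the acquisition metadata needed for radiometric correction:
per-band sensor calibration, a downwelling-light-sensor (DLS) irradiance
record and, optionally, calibrated-reflectance-panel (CRP) observations taken
before and after the flight.

On disk a capture is ``<captureid>_<band>.tif`` (16-bit grayscale for raw DN,
32-bit float for reflectance) plus ``<captureid>_metadata.json`` whose
per-band keys follow the camera's embedded metadata tag names
(``ExposureTime``, ``ISOSpeed``, ``BlackLevel``, ``RadiometricCalibration0-2``,
``VignettingCenter0-1``, ``VignettingPolynomial0-5``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from olivegrove.radiometric import (
    BandImage,
    CRPObservation,
    IrradianceObservation,
    RadiometricCalibration,
)

#: Canonical band order used throughout the package.
BANDS = ("blue", "green", "red", "nir", "rededge")


@dataclass
class MultispectralCapture:
    """Five band rasters with acquisition metadata for one UAV capture."""

    capture_id: str
    bands: dict[str, BandImage]
    calibration: dict[str, RadiometricCalibration]
    irradiance: Optional[IrradianceObservation] = None
    crp_pre: Optional[CRPObservation] = None
    crp_post: Optional[CRPObservation] = None
    timestamp: float = 0.0
    gsd: Optional[float] = None  # ground sample distance, cm/px

    def __post_init__(self) -> None:
        missing = set(BANDS) - set(self.bands)
        if missing:
            raise ValueError(f"capture {self.capture_id} missing bands: {sorted(missing)}")
        shapes = {b: img.values.shape for b, img in self.bands.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"band rasters differ in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands[BANDS[0]].values.shape

    @property
    def stage(self) -> str:
        stages = {img.stage for img in self.bands.values()}
        if len(stages) != 1:
            raise ValueError(f"bands at mixed stages: {stages}")
        return stages.pop()


def save_capture(capture: MultispectralCapture, out_dir: str | Path) -> Path:
    """Write band TIFFs and the metadata sidecar; returns the metadata path.

    Raw DN rasters are stored as 16-bit unsigned TIFF, anything else as
    32-bit float TIFF.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for band in BANDS:
        img = capture.bands[band]
        path = out / f"{capture.capture_id}_{band}.tif"
        if img.stage == "raw":
            tifffile.imwrite(path, img.values.astype(np.uint16))
        else:
            tifffile.imwrite(path, img.values.astype(np.float32))
    meta = {
        "capture_id": capture.capture_id,
        "timestamp": capture.timestamp,
        "stage": capture.stage,
        "gsd": capture.gsd,
        "bands": {b: capture.calibration[b].to_metadata() for b in BANDS},
        "dls": capture.irradiance.to_dict() if capture.irradiance else None,
        "crp": {
            "pre": capture.crp_pre.to_dict() if capture.crp_pre else None,
            "post": capture.crp_post.to_dict() if capture.crp_post else None,
        },
    }
    meta_path = out / f"{capture.capture_id}_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    return meta_path


def load_capture(capture_dir: str | Path, capture_id: str) -> MultispectralCapture:
    """Load a capture written by :func:`save_capture`."""
    d = Path(capture_dir)
    meta = json.loads((d / f"{capture_id}_metadata.json").read_text())
    stage = meta.get("stage", "raw")
    bands: dict[str, BandImage] = {}
    calibration: dict[str, RadiometricCalibration] = {}
    for band in BANDS:
        values = tifffile.imread(d / f"{capture_id}_{band}.tif")
        bands[band] = BandImage(np.asarray(values), band=band, stage=stage)
        calibration[band] = RadiometricCalibration.from_metadata(meta["bands"][band])
    irradiance = (
        IrradianceObservation.from_dict(meta["dls"]) if meta.get("dls") else None
    )
    crp = meta.get("crp") or {}
    return MultispectralCapture(
        capture_id=capture_id,
        bands=bands,
        calibration=calibration,
        irradiance=irradiance,
        crp_pre=CRPObservation.from_dict(crp["pre"]) if crp.get("pre") else None,
        crp_post=CRPObservation.from_dict(crp["post"]) if crp.get("post") else None,
        timestamp=meta.get("timestamp", 0.0),
        gsd=meta.get("gsd"),
    )


def list_capture_ids(capture_dir: str | Path) -> list[str]:
    """Capture ids present in a directory (one metadata sidecar each)."""
    d = Path(capture_dir)
    return sorted(p.name[: -len("_metadata.json")] for p in d.glob("*_metadata.json"))
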