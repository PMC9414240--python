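"""Seeded synthetic olive-grove captures.

The study conditions this generator emulates are a traditionally arranged
grove: canopies on a near-regular planting lattice, thick and patchy weed
cover between them, bare soil elsewhere and optional canopy shadows. Each
class gets a per-band mean reflectance with Gaussian pixel noise; olive and
weed are deliberately close in the green band but separated in red, which is
the hard case the detection method targets. Raw digital numbers are produced
by *inverting* the radiometric model (reflectance -> radiance -> DN with the
default camera calibration), so the radiometric module is exercised
end-to-end: correcting the emitted DN must recover the class reflectances.

Everything is deterministic for a fixed seed, and captures are written in
exactly the file layout the pipeline consumes, so fixtures are
indistinguishable from field data to every other module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from olivegrove.capture import BANDS, MultispectralCapture
from olivegrove.features import LabelledPixel
from olivegrove.radiometric import (
    DEFAULT_CALIBRATION,
    DEFAULT_PANEL_HDRF,
    BandImage,
    CRPObservation,
    IrradianceObservation,
    incoming_irradiance,
    row_correction,
    vignette_map,
)

#: Per-class mean reflectance (blue, green, red, nir, rededge). Olive and
#: weed nearly coincide in green and differ mostly in red/NIR; soil is
#: bright and red-shifted; shadow is dark in every band. Configuration
#: values, not claims about real spectra.
DEFAULT_REFLECTANCE = {
    "olive": {"blue": 0.030, "green": 0.080, "red": 0.040, "nir": 0.450, "rededge": 0.250},
    "weed": {"blue": 0.045, "green": 0.090, "red": 0.095, "nir": 0.400, "rededge": 0.220},
    "ground": {"blue": 0.120, "green": 0.180, "red": 0.250, "nir": 0.300, "rededge": 0.280},
    "shadow": {"blue": 0.012, "green": 0.018, "red": 0.015, "nir": 0.060, "rededge": 0.035},
}

_CLASS_CODES = {"ground": 0, "olive": 1, "weed": 2, "shadow": 3}
_CODE_CLASSES = {v: k for k, v in _CLASS_CODES.items()}


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class GroveScenario:
    """Parameters of one synthetic grove capture."""

    width: int = 192
    height: int = 192
    spacing: float = 26.0  # planting lattice spacing, px
    orientation: float = 0.0  # lattice rotation, rad
    jitter: float = 1.5  # positional jitter sigma, px
    canopy_radius_mean: float = 5.5  # px
    canopy_radius_sigma: float = 0.6
    weed_fraction: float = 0.35  # target weed cover of the non-canopy ground
    shadow_offset: Optional[tuple[float, float]] = None  # (dx, dy) px, None = no shadows
    reflectance: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REFLECTANCE.items()})
    noise_sigma: float = 0.008  # reflectance noise per band
    gsd: float = 12.8  # cm/px, metadata only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 2 * self.canopy_radius_mean:
            raise GenerationError("lattice spacing must exceed the canopy diameter")
        if not 0 <= self.weed_fraction <= 1:
            raise GenerationError("weed fraction must lie in [0, 1]")
        if self.width <= 0 or self.height <= 0:
            raise GenerationError("image dimensions must be positive")


@dataclass
class SyntheticCapture:
    """A rendered scenario: raw capture + every piece of ground truth."""

    capture: MultispectralCapture  # raw DN + full metadata
    reflectance: dict[str, np.ndarray]  # noise-free-pipeline truth, band -> raster
    class_map: np.ndarray  # uint8, codes ground/olive/weed/shadow
    truth_mask: np.ndarray  # binary canopy mask
    centres: np.ndarray  # (n, 2) float, columns (x, y)
    labels: list[LabelledPixel]


def _lattice_centres(scenario: GroveScenario, rng: np.random.Generator) -> np.ndarray:
    """Jittered planting-lattice nodes whose canopies fit inside the frame."""
    c, s = np.cos(scenario.orientation), np.sin(scenario.orientation)
    span = max(scenario.width, scenario.height)
    n = int(np.ceil(span / scenario.spacing)) + 2
    margin = scenario.canopy_radius_mean + 3 * scenario.canopy_radius_sigma
    centres = []
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            u, v = i * scenario.spacing, j * scenario.spacing
            x = scenario.width / 2 + c * u - s * v
            y = scenario.height / 2 + s * u + c * v
            if scenario.jitter > 0:
                x += rng.normal(0, scenario.jitter)
                y += rng.normal(0, scenario.jitter)
            if margin <= x < scenario.width - margin and margin <= y < scenario.height - margin:
                centres.append((x, y))
    return np.array(centres) if centres else np.empty((0, 2))


def _fill_disc(grid: np.ndarray, x: float, y: float, radius: float, value: int) -> None:
    h, w = grid.shape
    x0, x1 = max(0, int(x - radius - 1)), min(w, int(x + radius + 2))
    y0, y1 = max(0, int(y - radius - 1)), min(h, int(y + radius + 2))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    grid[y0:y1, x0:x1][np.hypot(xx - x, yy - y) <= radius] = value


def render_class_map(
    scenario: GroveScenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Render the per-pixel class map and return it with the canopy centres."""
    grid = np.zeros((scenario.height, scenario.width), dtype=np.uint8)
    centres = _lattice_centres(scenario, rng)
    radii = np.maximum(
        rng.normal(scenario.canopy_radius_mean, scenario.canopy_radius_sigma, len(centres)),
        1.5,
    )
    # shadows first so canopies overwrite them where they overlap
    if scenario.shadow_offset is not None:
        dx, dy = scenario.shadow_offset
        for (x, y), r in zip(centres, radii):
            _fill_disc(grid, x + dx, y + dy, r, _CLASS_CODES["shadow"])
    # weed blobs on the remaining ground until the target cover is reached
    if scenario.weed_fraction > 0:
        target = scenario.weed_fraction
        ground_total = None
        for _ in range(4000):
            canopy_free = grid != _CLASS_CODES["olive"]
            if ground_total is None:
                ground_total = canopy_free.sum()
            weed_now = (grid == _CLASS_CODES["weed"]).sum()
            if weed_now >= target * ground_total:
                break
            r = rng.uniform(2.0, 6.0)
            x = rng.uniform(0, scenario.width)
            y = rng.uniform(0, scenario.height)
            _fill_disc(grid, x, y, r, _CLASS_CODES["weed"])
    for (x, y), r in zip(centres, radii):
        _fill_disc(grid, x, y, r, _CLASS_CODES["olive"])
    return grid, centres


def _reflectance_bands(
    scenario: GroveScenario, class_map: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    bands = {}
    for band in BANDS:
        means = np.array(
            [scenario.reflectance[_CODE_CLASSES[c]][band] for c in range(4)]
        )
        img = means[class_map]
        if scenario.noise_sigma > 0:
            img = img + rng.normal(0, scenario.noise_sigma, img.shape)
        bands[band] = np.maximum(img, 1e-4)
    return bands


def _irradiance_for(scenario: GroveScenario) -> IrradianceObservation:
    """DLS record chosen so the brightest scene reflectance stays in DN range."""
    theta_i, alpha, cf, w_dif = 1.0, 0.2, 0.9057, 0.167
    target_ei = 0.30  # W m-2 nm-1; keeps DN below saturation for HDRF <= 0.6
    geom = w_dif + np.cos(alpha) * np.sin(theta_i)
    e_s = target_ei / (np.sin(theta_i) + w_dif)
    e_dls = e_s * cf * geom
    return IrradianceObservation(
        e_dls={b: e_dls for b in BANDS},
        theta_i=theta_i,
        alpha=alpha,
        cf=cf,
        w_dif=w_dif,
        timestamp=500.0,
    )


def _dn_from_reflectance(
    hdrf_img: np.ndarray, e_i: float, calib=DEFAULT_CALIBRATION
) -> np.ndarray:
    """Invert the radiometric model: HDRF -> radiance -> raw DN counts."""
    h, w = hdrf_img.shape
    lr = hdrf_img * e_i / np.pi
    v = vignette_map(calib, w, h)
    r = np.asarray(row_correction(calib, np.arange(h, dtype=np.float64)))[:, None]
    dn = lr * (calib.g * calib.te) / calib.a1 / (v * r) * calib.dn_max + calib.dn_bl
    return np.clip(np.round(dn), 0, calib.dn_max).astype(np.uint16)


def _sample_labels(
    scenario: GroveScenario,
    capture_id: str,
    class_map: np.ndarray,
    bands: dict[str, np.ndarray],
    rng: np.random.Generator,
    per_class: int = 300,
) -> list[LabelledPixel]:
    labels: list[LabelledPixel] = []
    for cls, code in _CLASS_CODES.items():
        ys, xs = np.nonzero(class_map == code)
        if ys.size == 0:
            continue
        take = min(per_class, ys.size)
        idx = rng.choice(ys.size, size=take, replace=False)
        for i in idx:
            y, x = int(ys[i]), int(xs[i])
            labels.append(
                LabelledPixel(
                    capture_id=capture_id,
                    x=x,
                    y=y,
                    blue=float(bands["blue"][y, x]),
                    green=float(bands["green"][y, x]),
                    red=float(bands["red"][y, x]),
                    nir=float(bands["nir"][y, x]),
                    rededge=float(bands["rededge"][y, x]),
                    label=cls,
                )
            )
    return labels


def generate(scenario: GroveScenario, capture_id: str = "synthetic") -> SyntheticCapture:
    """Render a scenario into a raw-DN capture with full ground truth."""
    rng = np.random.default_rng(scenario.seed)
    class_map, centres = render_class_map(scenario, rng)
    bands = _reflectance_bands(scenario, class_map, rng)
    obs = _irradiance_for(scenario)
    e_i = incoming_irradiance(obs)
    # panel captures consistent with the panel's calibrated HDRF -> f_CRP = 1
    crp_kwargs = dict(
        radiance={b: DEFAULT_PANEL_HDRF[b] * e_i[b] / np.pi for b in BANDS},
        irradiance=dict(e_i),
        panel_hdrf=dict(DEFAULT_PANEL_HDRF),
    )
    raw_bands = {
        b: BandImage(_dn_from_reflectance(bands[b], e_i[b]), band=b, stage="raw")
        for b in BANDS
    }
    capture = MultispectralCapture(
        capture_id=capture_id,
        bands=raw_bands,
        calibration={b: DEFAULT_CALIBRATION for b in BANDS},
        irradiance=obs,
        crp_pre=CRPObservation(timestamp=0.0, **crp_kwargs),
        crp_post=CRPObservation(timestamp=1000.0, **crp_kwargs),
        timestamp=obs.timestamp,
        gsd=scenario.gsd,
    )
    truth_mask = (class_map == _CLASS_CODES["olive"]).astype(np.uint8)
    labels = _sample_labels(scenario, capture_id, class_map, bands, rng)
    return SyntheticCapture(
        capture=capture,
        reflectance=bands,
        class_map=class_map,
        truth_mask=truth_mask,
        centres=centres,
        labels=labels,
    )


def generate_probability_image(
    scenario: GroveScenario,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct probability-image fixture for the marking stage.

    Canopy pixels draw probabilities from U(0.7, 1.0), weed pixels from
    U(0.1, 0.6), everything else is 0; deterministic for a fixed seed.
    """
    rng = np.random.default_rng(scenario.seed)
    class_map, centres = render_class_map(scenario, rng)
    prob = np.zeros(class_map.shape, dtype=np.float32)
    olive = class_map == _CLASS_CODES["olive"]
    weed = class_map == _CLASS_CODES["weed"]
    prob[olive] = rng.uniform(0.7, 1.0, olive.sum())
    prob[weed] = rng.uniform(0.1, 0.6, weed.sum())
    return prob, centres
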