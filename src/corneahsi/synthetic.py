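"""Synthetic hyperspectral cornea scenes and the packaged 25-eye feature table.

No corneal hyperspectral image set is publicly deposited, so the pipeline is
exercised on generated cubes that reproduce the statistical structure the
analysis assumes:

* smooth visible-NIR reflectance spectra rising through 450-600 nm onto a
  near-infrared plateau, with a subtle band-dependent depression where the
  epithelium is abraded (injured tissue differs from healthy tissue only by
  a small additive offset concentrated in the 503-625 nm window);
* specular glare: small saturated blobs at the sensor maximum in every band;
* a dark-current offset and white-reference frame with mild column structure
  (pushbroom sensors vary along the slit axis);
* additive acquisition noise: a small independent (shot-like) component plus
  a dominant smooth illumination-drift field whose strength varies from band
  to band, as left by lamp flicker and scan-time variation after spatial
  binning — the nuisance that buries the injury in raw component images;
* a single spatially compact injury region with a smooth boundary covering
  5-20% of the frame.

The forward model per pixel and band is

    counts = dark + gain * (R / 100) * (white - dark) + noise

so that flat-field correction inverts the generator exactly in the
noise-free case.  The module also ships the printed 25-eye first-order
histogram feature table (11 healthy, 14 injured) as a CSV fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from .cube import HyperCube

__all__ = [
    "SpectrumModel",
    "SyntheticScene",
    "make_scene",
    "make_cohort",
    "published_feature_table",
]

#: Spline control points for the healthy corneal reflectance curve:
#: low in the blue, rising through 450-600 nm, plateauing in the NIR.
DEFAULT_CONTROL_WAVELENGTHS = (400.0, 450.0, 500.0, 550.0, 600.0, 700.0, 850.0, 1000.0)
DEFAULT_CONTROL_REFLECTANCE = (18.0, 22.0, 38.0, 52.0, 60.0, 64.0, 66.0, 65.0)

#: Injury offset: a smooth depression centred in the 503-625 nm window.
DEFAULT_DELTA_PEAK = -6.0  # % reflectance at the centre of the window
DEFAULT_DELTA_CENTER = 564.0  # nm
DEFAULT_DELTA_WIDTH = 55.0  # nm (Gaussian scale)


def _default_wavelengths(n_bands: int = 256) -> np.ndarray:
    return np.linspace(400.0, 1000.0, n_bands)


@dataclass
class SpectrumModel:
    """Per-band reflectance model for healthy and injured corneal tissue.

    Attributes
    ----------
    wavelengths
        Band grid in nm (default 400-1000 nm over 256 bands).
    base_curve
        Healthy reflectance per band, % in [0, 100].
    injured_delta
        Additive per-band offset (%), applied inside the injury region.
        Small relative to the base curve (|delta| <= 20% of base) and
        nonzero at least across the 503-625 nm window.
    noise_sd
        Total additive acquisition-noise amplitude, in % reflectance units.
        Split between an independent per-pixel component and a smooth
        band-varying illumination-drift field by ``drift_fraction``.
    drift_fraction
        Fraction of ``noise_sd`` carried by the smooth drift field (the
        remainder is independent pixel noise).  Zero gives pure white noise.
    """

    wavelengths: np.ndarray = field(default_factory=_default_wavelengths)
    base_curve: np.ndarray | None = None
    injured_delta: np.ndarray | None = None
    noise_sd: float = 0.8
    drift_fraction: float = 0.75

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.base_curve is None:
            spline = CubicSpline(DEFAULT_CONTROL_WAVELENGTHS, DEFAULT_CONTROL_REFLECTANCE)
            self.base_curve = spline(self.wavelengths)
        self.base_curve = np.asarray(self.base_curve, dtype=np.float64)
        if self.injured_delta is None:
            z = (self.wavelengths - DEFAULT_DELTA_CENTER) / DEFAULT_DELTA_WIDTH
            self.injured_delta = DEFAULT_DELTA_PEAK * np.exp(-(z**2))
        self.injured_delta = np.asarray(self.injured_delta, dtype=np.float64)
        if self.base_curve.shape != self.wavelengths.shape:
            raise ValueError("base_curve length must match wavelength grid")
        if self.injured_delta.shape != self.wavelengths.shape:
            raise ValueError("injured_delta length must match wavelength grid")
        for name, curve in (("base_curve", self.base_curve), ("injured", self.injured_curve())):
            if curve.min() < 0 or curve.max() > 100:
                raise ValueError(f"{name} leaves the [0, 100]% reflectance range")
        window = (self.wavelengths >= 503) & (self.wavelengths <= 625)
        if window.any() and not np.any(np.abs(self.injured_delta[window]) > 0):
            raise ValueError("injured_delta vanishes on the 503-625 nm window")
        rel = np.abs(self.injured_delta) / np.maximum(self.base_curve, 1e-12)
        if rel.max() > 0.20:
            raise ValueError("injured_delta exceeds 20% of the base curve")

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths)

    def injured_curve(self) -> np.ndarray:
        return self.base_curve + self.injured_delta


@dataclass
class SyntheticScene:
    """One generated acquisition: raw cube, references, and ground truth."""

    cube: HyperCube
    dark: np.ndarray
    white: np.ndarray
    injury_mask: np.ndarray
    glare_mask: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if self.label not in ("healthy", "injured"):
            raise ValueError(f"label must be 'healthy' or 'injured', got {self.label!r}")
        if (self.label == "healthy") != (not self.injury_mask.any()):
            raise ValueError("injury_mask must be empty iff label is 'healthy'")
        if not np.all(self.dark < self.white):
            raise ValueError("dark frame must lie strictly below white frame")


def _smooth_blob(shape, center, radius, rng, smooth_sigma=2.0):
    """Binary blob: a disk with a smoothed, slightly irregular boundary."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dist = np.hypot(rr - center[0], cc - center[1])
    # Perturb the radius with a low-frequency random field, then smooth and
    # threshold so the boundary is irregular but the mask stays binary.
    bump = gaussian_filter(rng.standard_normal(shape), 6.0)
    bump *= 0.15 * radius / max(np.abs(bump).max(), 1e-12)
    soft = gaussian_filter((dist <= radius + bump).astype(float), smooth_sigma)
    return soft >= 0.5


def make_scene(
    model: SpectrumModel,
    size: tuple[int, int] = (128, 128),
    label: str = "healthy",
    injury_geometry: tuple[int, int, int] | None = None,
    glare_count: int = 2,
    seed: int = 0,
    gain: float = 1.0,
    sensor_max: float = 4095.0,
    dark_level: float = 96.0,
    white_level: float = 3072.0,
) -> SyntheticScene:
    """Generate one raw scene with reference frames and ground-truth masks.

    Parameters
    ----------
    model
        Spectral model shared by the cohort.
    size
        Spatial frame ``(rows, cols)``; at least 32 x 32.
    label
        ``'healthy'`` or ``'injured'``.
    injury_geometry
        ``(row, col, radius)`` of the injury blob, or None for a random blob
        covering 5-20% of the frame.  Must lie inside the frame.
    glare_count
        Number of saturated specular blobs.
    seed
        Scene seed; identical seeds give bit-identical scenes.

    Returns
    -------
    SyntheticScene
        Raw cube in sensor counts plus dark/white frames and masks.
    """
    rows, cols = size
    if rows < 32 or cols < 32:
        raise ValueError(f"frame must be at least 32x32, got {size}")
    n_bands = model.n_bands
    if n_bands < 8:
        raise ValueError(f"need at least 8 bands, got {n_bands}")
    rng = np.random.default_rng(seed)

    # Reference frames: column structure mimicking slit-axis response
    # variation of a pushbroom sensor.  2-D, broadcast over bands.
    dark = dark_level + 3.0 * rng.random(cols)[None, :] * np.ones((rows, 1))
    white = white_level + 120.0 * rng.random(cols)[None, :] * np.ones((rows, 1))

    # Tissue reflectance: base curve everywhere, delta inside the injury.
    refl = np.broadcast_to(model.base_curve, (rows, cols, n_bands)).copy()
    injury_mask = np.zeros((rows, cols), dtype=bool)
    if label == "injured":
        if injury_geometry is None:
            frac = rng.uniform(0.05, 0.20)
            radius = np.sqrt(frac * rows * cols / np.pi)
            margin = int(np.ceil(radius)) + 2
            if 2 * margin >= min(rows, cols):
                raise ValueError("frame too small for the requested injury area")
            center = (rng.integers(margin, rows - margin), rng.integers(margin, cols - margin))
        else:
            r0, c0, radius = injury_geometry
            if not (0 <= r0 - radius and r0 + radius < rows and 0 <= c0 - radius and c0 + radius < cols):
                raise ValueError(f"injury geometry {injury_geometry} outside frame {size}")
            center = (r0, c0)
        injury_mask = _smooth_blob((rows, cols), center, radius, rng)
        refl[injury_mask] += model.injured_delta
    elif label != "healthy":
        raise ValueError(f"unknown label {label!r}")

    # Forward model to sensor counts.
    span = (white - dark)[:, :, None]
    counts = dark[:, :, None] + gain * (refl / 100.0) * span
    if model.noise_sd > 0:
        w_drift = float(np.clip(model.drift_fraction, 0.0, 1.0))
        noise = (1.0 - w_drift) * rng.standard_normal(counts.shape)
        if w_drift > 0:
            # Smooth illumination drift: one low-frequency field per band,
            # partially coherent across bands (common field + band-varying
            # strength + an independent smooth residual per band).
            common = gaussian_filter(rng.standard_normal((rows, cols)), 12.0)
            common /= max(common.std(), 1e-12)
            strength = 1.0 + 0.5 * rng.standard_normal(n_bands)
            resid = gaussian_filter(
                rng.standard_normal((rows, cols, n_bands)), (12.0, 12.0, 0.0)
            )
            resid /= max(resid.std(), 1e-12)
            drift = common[:, :, None] * strength[None, None, :] + 0.5 * resid
            drift /= max(drift.std(), 1e-12)
            noise = noise + w_drift * drift
        counts = counts + gain * (model.noise_sd / 100.0) * span * noise

    # Specular glare: saturated disks in every band.
    glare_mask = np.zeros((rows, cols), dtype=bool)
    for _ in range(glare_count):
        gr = int(rng.integers(3, 7))
        gcenter = (rng.integers(gr, rows - gr), rng.integers(gr, cols - gr))
        rr, cc = np.mgrid[:rows, :cols]
        glare_mask |= np.hypot(rr - gcenter[0], cc - gcenter[1]) <= gr
    counts = np.clip(counts, 0.0, sensor_max)
    counts[glare_mask] = sensor_max

    cube = HyperCube(counts, model.wavelengths.copy(), kind="raw")
    return SyntheticScene(cube, dark, white, injury_mask, glare_mask, label)


def make_cohort(
    n_healthy: int,
    n_injured: int,
    model: SpectrumModel,
    seed: int = 0,
    **scene_kwargs,
) -> list[SyntheticScene]:
    """Generate a labelled cohort of scenes.

    Labels are laid out healthy-first then shuffled by the master seed;
    scene ``i`` uses child seed ``seed + i``, so the cohort is fully
    reproducible from the master seed alone.
    """
    if n_healthy < 0 or n_injured < 0:
        raise ValueError("cohort counts must be non-negative")
    labels = ["healthy"] * n_healthy + ["injured"] * n_injured
    order = np.random.default_rng(seed).permutation(len(labels))
    labels = [labels[i] for i in order]
    return [
        make_scene(model, label=lab, seed=seed + i, **scene_kwargs)
        for i, lab in enumerate(labels)
    ]


def published_feature_table() -> pd.DataFrame:
    """The printed 25-eye first-order histogram feature table.

    Columns: ``eye_id, label, mean, std, skewness, kurtosis``; 11 healthy
    rows followed by 14 injured rows, values verbatim as published.
    """
    with resources.files("corneahsi.data").joinpath("published_features.csv").open() as fh:
        return pd.read_csv(fh)
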