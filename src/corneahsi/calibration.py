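"""Flat-field correction of raw cubes to relative reflectance.

Pushbroom sensors are normalised against two reference acquisitions: a dark
frame recorded with the lens capped (sensor dark current) and a white frame
of a near-perfect diffuse reflector (Spectralon).  Per pixel and band the
relative reflectance is

    R = (I_sample - I_dark) / (I_white - I_dark) * 100  [%]

Pixels where the white and dark frames coincide carry no usable dynamic
range (dead or stuck sensor elements); they are flagged as defective and
masked (NaN) rather than propagated as infinities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import HyperCube

__all__ = ["ReferenceFrames", "find_defective_pixels", "flat_field_correct"]


@dataclass
class ReferenceFrames:
    """Dark-current and white-reference images.

    Either 2-D frames broadcast over all bands, or full ``M x N x L`` stacks.
    """

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=np.float64)
        self.white = np.asarray(self.white, dtype=np.float64)
        if self.dark.shape != self.white.shape:
            raise ValueError(
                f"dark shape {self.dark.shape} != white shape {self.white.shape}"
            )
        if self.dark.ndim not in (2, 3):
            raise ValueError("reference frames must be 2-D or 3-D")


def _broadcast(refs: ReferenceFrames, cube_shape: tuple[int, int, int]):
    dark, white = refs.dark, refs.white
    if dark.ndim == 2:
        dark = dark[:, :, None]
        white = white[:, :, None]
    if dark.shape[:2] != cube_shape[:2] or dark.shape[2] not in (1, cube_shape[2]):
        raise ValueError(
            f"reference shape {refs.dark.shape} incompatible with cube shape {cube_shape}"
        )
    return dark, white


def find_defective_pixels(refs: ReferenceFrames, tolerance: float | None = None) -> np.ndarray:
    """Flag pixels whose usable dynamic range ``white - dark`` is ≤ tolerance.

    The default tolerance is ``1e-6`` of the white frame's dynamic range.
    Returns a boolean mask of the reference frame shape (True = defective).
    """
    span = refs.white - refs.dark
    if tolerance is None:
        dyn = float(refs.white.max() - refs.dark.min())
        tolerance = 1e-6 * dyn if dyn > 0 else 0.0
    return span <= tolerance


def flat_field_correct(
    raw: HyperCube,
    refs: ReferenceFrames,
    clip: tuple[float, float] | None = (0.0, 150.0),
    tolerance: float | None = None,
) -> HyperCube:
    """Convert raw counts to percent relative reflectance.

    Parameters
    ----------
    raw
        Raw-kind cube of sensor counts.
    refs
        Dark and white reference frames (2-D band-broadcast or per-band 3-D).
    clip
        ``(lo, hi)`` clip bounds in % applied after correction, or None to
        disable.  The default upper bound of 150% tolerates specular glare
        exceeding the diffuse white reference while keeping later 8-bit
        quantisation well defined.
    tolerance
        Defective-pixel threshold forwarded to :func:`find_defective_pixels`.

    Defective pixels are returned as NaN in every band.
    """
    dark, white = _broadcast(refs, raw.shape)
    defect = find_defective_pixels(refs, tolerance)
    if defect.all():
        raise ValueError("all reference pixels are defective (white <= dark everywhere)")
    denom = white - dark
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.data - dark) / denom * 100.0
    if clip is not None:
        refl = np.clip(refl, clip[0], clip[1])
    if defect.ndim == 2:
        refl[defect, :] = np.nan
    else:
        refl[defect] = np.nan
    return HyperCube(refl, raw.wavelengths.copy(), kind="reflectance")
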