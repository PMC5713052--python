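"""Cornea localisation by FFT-based template correlation and ROI extraction.

The cornea is found in a single band image by normalised cross-correlation
(zero-mean, unit-norm per window) computed in the frequency domain, then the
cube is cropped to the matched bounding box and resampled to a fixed size
(100 x 100 by default) so that every eye enters the enhancement chain on the
same spatial grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.feature import match_template as _ncc

from .cube import HyperCube

__all__ = ["TemplateMatch", "match_template", "crop_resize"]


@dataclass
class TemplateMatch:
    """Result of a normalised cross-correlation search.

    ``peak_offset`` is the (row, col) of the template's top-left corner at
    the correlation maximum; ties resolve to the smallest row, then column.
    """

    correlation_map: np.ndarray
    peak_offset: tuple[int, int]
    peak_value: float


def match_template(image: np.ndarray, template: np.ndarray) -> TemplateMatch:
    """Locate ``template`` in ``image`` by FFT-based normalised correlation.

    The correlation map has one entry per valid placement and values in
    [-1, 1]; +1 is an exact match, -1 an exact anti-match.
    """
    image = np.asarray(image, dtype=np.float64)
    template = np.asarray(template, dtype=np.float64)
    if image.ndim != 2 or template.ndim != 2:
        raise ValueError("image and template must be 2-D")
    if template.shape[0] >= image.shape[0] or template.shape[1] >= image.shape[1]:
        raise ValueError(
            f"template {template.shape} must be strictly smaller than image {image.shape}"
        )
    if np.ptp(template) == 0:
        raise ValueError("template has zero variance; correlation is undefined")
    corr = _ncc(image, template, pad_input=False)
    corr = np.clip(corr, -1.0, 1.0)
    flat = int(np.argmax(corr))  # first maximum in row-major order
    peak = np.unravel_index(flat, corr.shape)
    return TemplateMatch(corr, (int(peak[0]), int(peak[1])), float(corr[peak]))


def crop_resize(
    cube: HyperCube,
    bbox: tuple[int, int, int, int],
    out_size: tuple[int, int] = (100, 100),
) -> HyperCube:
    """Crop every band to ``bbox`` and resample to ``out_size``.

    ``bbox`` is ``(row, col, height, width)`` in 0-based pixel coordinates.
    Resampling is bilinear on a corner-aligned grid (the first and last
    samples of the crop map exactly onto the first and last output pixels),
    so a crop already at the target size passes through unchanged and a
    linear ramp keeps its endpoints.
    """
    r, c, h, w = bbox
    rows, cols, n_bands = cube.shape
    if r < 0 or c < 0 or h <= 0 or w <= 0 or r + h > rows or c + w > cols:
        raise ValueError(f"bbox {bbox} outside cube extents {cube.shape[:2]}")
    crop = cube.data[r : r + h, c : c + w, :]
    if (h, w) == tuple(out_size):
        return HyperCube(crop.copy(), cube.wavelengths.copy(), cube.kind)
    gr = np.linspace(0, h - 1, out_size[0])
    gc = np.linspace(0, w - 1, out_size[1])
    coords = np.meshgrid(gr, gc, indexing="ij")
    out = np.empty((out_size[0], out_size[1], n_bands))
    for b in range(n_bands):
        out[:, :, b] = map_coordinates(crop[:, :, b], coords, order=1, mode="nearest")
    return HyperCube(out, cube.wavelengths.copy(), cube.kind)
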