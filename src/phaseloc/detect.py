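"""Pixel-level 3D detection of single molecules by matched filtering.

A stack of model PSF templates is built on an axial grid, each frame is
cross-correlated with every template (zero-mean normalized cross-correlation
over the sliding window, so scores live in [-1, 1] and the detection
threshold is scale-free), and candidates are the 26-connected local maxima
of the resulting (z, y, x) correlation volume above threshold, ordered by
decreasing score.  Maxima closer than half a template to the frame border
are discarded, and laterally overlapping candidates are suppressed (the
downstream localizer is a single-emitter fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter
from skimage.feature import match_template

from .optics import PupilModel, psf_model

__all__ = ["TemplateStack", "Candidate", "build_templates", "detect"]

DEFAULT_THRESHOLD = 0.2


@dataclass
class TemplateStack:
    """Model PSF images on an axial grid, used as matched filters."""

    templates: np.ndarray   # (n_z, window, window)
    z_values: np.ndarray    # (n_z,) nm
    window: int

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        self.z_values = np.asarray(self.z_values, dtype=float)
        if self.templates.shape[0] != self.z_values.size:
            raise ValueError("template count must match z grid")
        if np.any(self.templates.sum(axis=(1, 2)) <= 0):
            raise ValueError("templates must have positive total intensity")


@dataclass(order=True)
class Candidate:
    """One pixel-level detection: position, template index and ZNCC score."""

    score: float
    frame: int = 0
    px: int = 0
    py: int = 0
    z_index: int = 0

    def __post_init__(self) -> None:
        if not -1.0001 <= self.score <= 1.0001:
            raise ValueError("ZNCC score must lie in [-1, 1]")


def build_templates(pupil: PupilModel, z_min: float, z_max: float,
                    dz: float | None = None, window: int = 25) -> TemplateStack:
    """Model PSFs at x = y = 0 for z in {z_min, z_min + dz, ..., z_max}.

    ``dz`` defaults to the pixel size, matching lateral and axial detection
    granularity.
    """
    if z_max <= z_min:
        raise ValueError("need z_max > z_min")
    if dz is None:
        dz = pupil.optics.pixel_size
    if dz <= 0:
        raise ValueError("dz must be positive")
    n = int(round((z_max - z_min) / dz)) + 1
    z = z_min + dz * np.arange(n)
    templates = psf_model(pupil, 0.0, 0.0, z, window=window)
    return TemplateStack(templates=templates, z_values=z, window=window)


def correlation_volume(frame: np.ndarray, templates: TemplateStack) -> np.ndarray:
    """ZNCC of the frame against each template, shape (n_z, H, W).

    Uses FFT-based sliding-window normalized cross-correlation; the map is
    frame-sized with the score at the template-center position.
    """
    frame = np.asarray(frame, dtype=float)
    if min(frame.shape) < templates.window:
        raise ValueError("frame smaller than the template window")
    return np.stack([match_template(frame, t, pad_input=True)
                     for t in templates.templates])


def detect(frame: np.ndarray, templates: TemplateStack,
           threshold: float = DEFAULT_THRESHOLD,
           frame_index: int = 0) -> list[Candidate]:
    """Detect molecules in one frame; candidates sorted by decreasing score.

    Local maxima use strict 26-connectivity in (z_index, row, col); ties
    break toward lower z_index then row-major order.  Candidates within half
    a template of the border are dropped; of laterally overlapping
    candidates (closer than half a template) only the best survives.
    """
    vol = correlation_volume(frame, templates)
    footprint = np.ones((3, 3, 3), dtype=bool)
    is_max = (vol == maximum_filter(vol, footprint=footprint, mode="nearest"))
    is_max &= vol > threshold
    half = templates.window // 2
    zi, yi, xi = np.nonzero(is_max)
    h, w = frame.shape
    keep = ((yi >= half) & (yi < h - half) & (xi >= half) & (xi < w - half))
    zi, yi, xi = zi[keep], yi[keep], xi[keep]
    order = np.lexsort((xi, yi, zi, -vol[zi, yi, xi]))
    cands: list[Candidate] = []
    min_d2 = (templates.window / 2.0) ** 2
    for k in order:
        px, py, z_index = int(xi[k]), int(yi[k]), int(zi[k])
        if any((px - c.px) ** 2 + (py - c.py) ** 2 < min_d2 for c in cands):
            continue
        cands.append(Candidate(score=float(vol[z_index, py, px]),
                               frame=frame_index, px=px, py=py,
                               z_index=z_index))
    return cands
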