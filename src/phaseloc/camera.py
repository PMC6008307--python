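"""Camera conversion, bead-stack image formation and the Poisson likelihood.

Fitting always operates in photon units.  Raw camera counts (ADU) are
converted by ``photons = (adu - offset) / gain`` clipped at zero; for sCMOS
cameras with per-pixel gain/offset/readout noise the standard
variance-matching approximation is used: the per-pixel readout variance
(expressed in photons^2) is added to both data and model and the result is
treated as Poisson distributed.

The bead calibration model for bead ``s``, focal plane ``k`` and pixel ``i``
is ``M = A[s,k] * PSF_i(dx_s, dy_s, z_k + dz_s) + B_s(i)``, with per-plane
amplitudes (photobleaching) and a second-order polynomial background
``B = b0 x^2 + b1 y^2 + b2 xy + b3 x + b4 y + b5`` evaluated on centered,
window-normalized coordinates in [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .optics import PupilModel, psf_model

__all__ = [
    "CameraModel",
    "BeadStackSet",
    "CalibrationParams",
    "background_poly",
    "window_coords",
    "model_bead_stack",
    "neg_log_likelihood",
    "MODEL_FLOOR",
]

log = logging.getLogger(__name__)

# positivity floor (photons) applied to the model before taking logs
MODEL_FLOOR = 1e-6


@dataclass
class CameraModel:
    """Photon-conversion and noise model of the detector.

    ``mode`` is ``"emccd"`` (uniform gain/offset, pure Poisson) or
    ``"scmos"`` (scalar or per-pixel maps, readout variance in photons^2
    added through the variance-matching approximation).
    """

    gain: float | np.ndarray = 1.0
    offset: float | np.ndarray = 0.0
    read_noise_var: float | np.ndarray = 0.0
    mode: str = "emccd"

    def __post_init__(self) -> None:
        if self.mode not in ("emccd", "scmos"):
            raise ValueError(f"unknown camera mode {self.mode!r}")
        if np.any(np.asarray(self.gain) <= 0):
            raise ValueError("gain must be positive")
        if np.any(np.asarray(self.read_noise_var) < 0):
            raise ValueError("read_noise_var must be >= 0")

    def adu_to_photons(self, adu: np.ndarray) -> np.ndarray:
        return np.clip((np.asarray(adu, dtype=float) - self.offset) / self.gain,
                       0.0, None)

    def photons_to_adu(self, photons: np.ndarray) -> np.ndarray:
        return np.asarray(photons, dtype=float) * self.gain + self.offset

    def variance_offset(self) -> float | np.ndarray:
        """Per-pixel additive pseudo-count for the sCMOS approximation."""
        return self.read_noise_var if self.mode == "scmos" else 0.0


@dataclass
class BeadStackSet:
    """S calibration z-stacks (photon units) with their focal-plane positions."""

    stacks: list[np.ndarray]
    z_planes: np.ndarray
    camera: CameraModel = field(default_factory=CameraModel)

    def __post_init__(self) -> None:
        self.z_planes = np.asarray(self.z_planes, dtype=float)
        if not self.stacks:
            raise ValueError("at least one bead stack is required")
        shape = self.stacks[0].shape
        for s in self.stacks:
            if s.ndim != 3 or s.shape != shape:
                raise ValueError("all stacks must share shape (K, w, w)")
        if shape[0] != self.z_planes.size:
            raise ValueError("z_planes length must match plane count")
        if np.any(np.diff(self.z_planes) <= 0):
            raise ValueError("z_planes must be strictly increasing")

    @property
    def n_beads(self) -> int:
        return len(self.stacks)

    @property
    def n_planes(self) -> int:
        return self.z_planes.size

    @property
    def window(self) -> int:
        return self.stacks[0].shape[-1]


@dataclass
class CalibrationParams:
    """Full phase-retrieval parameter vector: pupil + per-bead nuisances."""

    pupil: PupilModel
    amplitudes: list[np.ndarray]    # per bead: (K,) photons
    backgrounds: list[np.ndarray]   # per bead: (6,) polynomial coefficients
    offsets: list[np.ndarray]       # per bead: (dx, dy, dz) in nm

    def __post_init__(self) -> None:
        self.amplitudes = [np.asarray(a, dtype=float) for a in self.amplitudes]
        self.backgrounds = [np.asarray(b, dtype=float) for b in self.backgrounds]
        self.offsets = [np.asarray(o, dtype=float) for o in self.offsets]
        if not (len(self.amplitudes) == len(self.backgrounds) == len(self.offsets)):
            raise ValueError("per-bead parameter lists must have equal length")
        for a in self.amplitudes:
            if np.any(a < 0):
                raise ValueError("amplitudes must be >= 0")
        for b in self.backgrounds:
            if b.shape != (6,):
                raise ValueError("backgrounds must have 6 coefficients")
        for o in self.offsets:
            if o.shape != (3,) or not np.all(np.isfinite(o)):
                raise ValueError("offsets must be finite (dx, dy, dz)")

    @property
    def n_beads(self) -> int:
        return len(self.amplitudes)


def window_coords(window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered pixel coordinates normalized to [-1, 1] over a square window.

    Returns ``(X, Y)`` with x along columns and y along rows.
    """
    half = (window - 1) / 2.0
    c = (np.arange(window) - half) / max(half, 1.0)
    y, x = np.meshgrid(c, c, indexing="ij")
    return x, y


def background_poly(b: Sequence[float], x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Second-order polynomial background b0 x^2 + b1 y^2 + b2 xy + b3 x + b4 y + b5."""
    b = np.asarray(b, dtype=float)
    if b.shape != (6,):
        raise ValueError("expected 6 polynomial coefficients")
    return (b[0] * x ** 2 + b[1] * y ** 2 + b[2] * x * y
            + b[3] * x + b[4] * y + b[5])


def background_basis(window: int) -> np.ndarray:
    """The six polynomial basis maps, shape (6, window, window)."""
    x, y = window_coords(window)
    return np.stack([x ** 2, y ** 2, x * y, x, y, np.ones_like(x)])


def model_bead_stack(params: CalibrationParams, z_planes: np.ndarray,
                     window: int) -> list[np.ndarray]:
    """Model stacks M[s][k] = A[s,k] * PSF(dx_s, dy_s, z_k + dz_s) + B_s."""
    z_planes = np.asarray(z_planes, dtype=float)
    x, y = window_coords(window)
    out = []
    for a, b, (dx, dy, dz) in zip(params.amplitudes, params.backgrounds,
                                  params.offsets):
        psf = psf_model(params.pupil, dx, dy, z_planes + dz, window=window)
        bg = background_poly(b, x, y)
        out.append(a[:, None, None] * psf + bg[None, :, :])
    return out


def neg_log_likelihood(model: np.ndarray, data: np.ndarray,
                       camera: CameraModel | None = None) -> float:
    """Poisson negative log likelihood -sum(I log M - M), constants dropped.

    Non-positive model pixels are clamped at ``MODEL_FLOOR`` (counted and
    logged).  In sCMOS mode the per-pixel readout variance is added to both
    data and model first.
    """
    model = np.asarray(model, dtype=float)
    data = np.asarray(data, dtype=float)
    if camera is not None and camera.mode == "scmos":
        v = camera.variance_offset()
        model = model + v
        data = data + v
    n_clamped = int(np.count_nonzero(model < MODEL_FLOOR))
    if n_clamped:
        log.debug("neg_log_likelihood: clamped %d non-positive model pixels",
                  n_clamped)
        model = np.maximum(model, MODEL_FLOOR)
    return float(np.sum(model - data * np.log(model)))
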