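"""Pupil-plane optics and the continuous PSF forward model.

The point spread function (PSF) of the microscope is modeled by scalar
diffraction: the emission field in the back focal plane (pupil) is a unit
amplitude wave restricted to the numerical-aperture disk, carrying a phase
with three contributions,

* an engineered / aberration phase ``Phi`` expanded on Zernike polynomials
  (Noll single-index convention, unit-RMS normalization, coefficients in
  radians; piston/tip/tilt excluded since they do not change the PSF shape),
* a lateral-position ramp ``2*pi*(x*kx + y*ky)``,
* an axial defocus term ``2*pi*(kz2*z - kz1*f)`` with
  ``kz{1,2} = sqrt((n{1,2}/lambda)^2 - kx^2 - ky^2)`` accounting for the
  refractive-index mismatch between immersion medium (n1) and sample (n2);
  ``f`` is the coverslip-to-focal-plane distance.

The image-domain intensity is the squared modulus of the Fourier transform
of that field, optionally convolved with an isotropic Gaussian of standard
deviation ``blur_sigma`` pixels that absorbs residual non-modeled blur.
Intensities are normalized so the unaberrated, index-matched, in-focus PSF
sums to one over the computation grid: PSF values are then per-pixel photon
fractions and amplitudes are photon counts.

Everything is evaluated on an ``fft_size``-squared grid with k-space spacing
``1/(fft_size*pixel_size)``, so image-plane pixels have the physical pixel
pitch.  Analytic derivatives of the PSF with respect to emitter position,
Zernike coefficients and blur are provided for maximum-likelihood fitting
and Fisher-information computations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "OpticsConfig",
    "PupilModel",
    "zernike_nm",
    "zernike_basis",
    "phase_from_coeffs",
    "psf_theoretical",
    "psf_model",
    "psf_and_derivatives",
    "crop_center",
]

PUPIL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Zernike polynomials (Noll indexing, unit RMS over the disk)
# ---------------------------------------------------------------------------

def zernike_nm(j: int) -> tuple[int, int]:
    """Map a Noll single index ``j`` (1-based) to radial/azimuthal orders.

    Returns ``(n, m)`` with signed ``m``: positive for cosine terms, negative
    for sine terms.  Noll's convention assigns cosine terms to even ``j`` and
    sine terms to odd ``j``.
    """
    if not isinstance(j, (int, np.integer)) or j < 1:
        raise ValueError(f"Noll index must be an integer >= 1, got {j!r}")
    n = int((-1.0 + math.sqrt(8 * (j - 1) + 1)) / 2.0)
    p = j - (n * (n + 1)) // 2
    k = n % 2
    m = 2 * ((p + k) // 2) - k
    if m != 0 and j % 2 != 0:
        m = -m
    return n, m


def _radial_poly(n: int, m: int, r: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r)
    for k in range((n - m) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)
             / (math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)))
        out += c * r ** (n - 2 * k)
    return out


def zernike_basis(j: int, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Evaluate the j-th Noll Zernike polynomial on normalized pupil coords.

    ``(u, v)`` are Cartesian coordinates normalized to the aperture radius;
    points with ``u^2 + v^2 > 1`` map to zero.  Normalization is unit RMS
    over the unit disk (Noll): ``sqrt(n+1)`` for m == 0, ``sqrt(2(n+1))``
    otherwise.
    """
    n, m = zernike_nm(j)
    r = np.hypot(u, v)
    inside = r <= 1.0
    theta = np.arctan2(v, u)
    rad = _radial_poly(n, abs(m), np.where(inside, r, 0.0))
    if m == 0:
        z = math.sqrt(n + 1) * rad
    elif m > 0:
        z = math.sqrt(2 * (n + 1)) * rad * np.cos(m * theta)
    else:
        z = math.sqrt(2 * (n + 1)) * rad * np.sin(-m * theta)
    return np.where(inside, z, 0.0)


# ---------------------------------------------------------------------------
# Configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticsConfig:
    """Fixed optical parameters of the imaging system.

    Parameters
    ----------
    na : numerical aperture of the objective.
    wavelength : emission wavelength in nm.
    n_immersion : refractive index of the immersion medium (n1).
    n_sample : refractive index of the sample medium (n2).
    pixel_size : image-plane pixel pitch in nm.
    focal_offset : coverslip-to-focal-plane distance ``f`` in nm.
    fft_size : side length of the pupil/image computation grid (even).
    """

    na: float = 1.2
    wavelength: float = 670.0
    n_immersion: float = 1.33
    n_sample: float = 1.33
    pixel_size: float = 110.0
    focal_offset: float = 0.0
    fft_size: int = 64

    def __post_init__(self) -> None:
        if self.na <= 0:
            raise ValueError("numerical aperture must be positive")
        if self.na > self.n_immersion:
            raise ValueError("NA cannot exceed the immersion index")
        if self.wavelength <= 0 or self.pixel_size <= 0:
            raise ValueError("wavelength and pixel_size must be positive")
        if self.fft_size < 16 or self.fft_size % 2:
            raise ValueError("fft_size must be an even integer >= 16")


class _PupilGrids:
    """Cached k-space grids for one OpticsConfig (centered convention)."""

    def __init__(self, optics: OpticsConfig) -> None:
        n = optics.fft_size
        dk = 1.0 / (n * optics.pixel_size)  # nm^-1
        idx = (np.arange(n) - n // 2) * dk
        self.ky, self.kx = np.meshgrid(idx, idx, indexing="ij")
        kr2 = self.kx ** 2 + self.ky ** 2
        k_na = optics.na / optics.wavelength
        self.aperture = kr2 <= k_na ** 2
        # normalized pupil coordinates for the Zernike basis
        self.u = self.kx / k_na
        self.v = self.ky / k_na
        kz1_sq = (optics.n_immersion / optics.wavelength) ** 2 - kr2
        kz2_sq = (optics.n_sample / optics.wavelength) ** 2 - kr2
        self.kz1 = np.sqrt(np.clip(kz1_sq, 0.0, None))
        # super-critical components (possible only when NA > n_sample) do not
        # propagate into the sample: hard amplitude cutoff
        self.propagating = kz2_sq > 0.0
        self.kz2 = np.sqrt(np.clip(kz2_sq, 0.0, None))
        self.amplitude = np.where(self.aperture & self.propagating, 1.0, 0.0)
        # Parseval: |FFT(aperture)|^2 sums to n^2 * aperture count
        self.norm = math.sqrt(float(self.aperture.sum()) * n * n)
        # frequency grids in cycles/pixel for the Fourier-space Gaussian blur
        fy = np.fft.fftfreq(n)
        self.f2 = fy[:, None] ** 2 + fy[None, :] ** 2

    def zernike(self, j: int) -> np.ndarray:
        return zernike_basis(j, self.u, self.v)


_GRID_CACHE: dict[OpticsConfig, _PupilGrids] = {}


def _grids(optics: OpticsConfig) -> _PupilGrids:
    g = _GRID_CACHE.get(optics)
    if g is None:
        g = _GRID_CACHE[optics] = _PupilGrids(optics)
    return g


@dataclass
class PupilModel:
    """Retrieved or engineered optical state that generates the PSF.

    ``coeffs`` holds Zernike coefficients c_4 .. c_{j_max} in radians
    (Noll-indexed, piston/tip/tilt excluded), so ``len(coeffs) == j_max - 3``.
    """

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    coeffs: np.ndarray = field(default_factory=lambda: np.zeros(33))
    blur_sigma: float = 0.7

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 1 or self.coeffs.size < 1:
            raise ValueError("coeffs must be a 1-D vector of length >= 1")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")

    @property
    def j_max(self) -> int:
        return self.coeffs.size + 3

    def coeff(self, j: int) -> float:
        """Zernike coefficient for Noll index ``j`` (4 <= j <= j_max)."""
        if not 4 <= j <= self.j_max:
            raise ValueError(f"index {j} outside [4, {self.j_max}]")
        return float(self.coeffs[j - 4])

    def with_coeffs(self, coeffs: np.ndarray) -> "PupilModel":
        return replace(self, coeffs=np.asarray(coeffs, dtype=float))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        o = self.optics
        return {
            "format_version": PUPIL_FORMAT_VERSION,
            "optics": {
                "na": o.na, "wavelength": o.wavelength,
                "n_immersion": o.n_immersion, "n_sample": o.n_sample,
                "pixel_size": o.pixel_size, "focal_offset": o.focal_offset,
                "fft_size": o.fft_size,
            },
            "j_max": self.j_max,
            "coeffs": [float(c) for c in self.coeffs],
            "blur_sigma": float(self.blur_sigma),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PupilModel":
        if d.get("format_version") != PUPIL_FORMAT_VERSION:
            raise ValueError(f"unsupported pupil format: {d.get('format_version')!r}")
        optics = OpticsConfig(**d["optics"])
        model = cls(optics=optics, coeffs=np.asarray(d["coeffs"], dtype=float),
                    blur_sigma=float(d["blur_sigma"]))
        if model.j_max != d["j_max"]:
            raise ValueError("j_max inconsistent with coefficient count")
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "PupilModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def phase_from_coeffs(pupil: PupilModel) -> np.ndarray:
    """Aberration phase map ``Phi = sum_j c_j Z_j`` on the aperture support."""
    g = _grids(pupil.optics)
    phi = np.zeros_like(g.u)
    for j, c in enumerate(pupil.coeffs, start=4):
        if c != 0.0:
            phi += c * g.zernike(j)
    return np.where(g.aperture, phi, 0.0)


def _pupil_field(pupil: PupilModel, x, y, z) -> np.ndarray:
    """Complex field amplitude(s) in the image plane, centered, shape
    ``z.shape + (n, n)``; normalized so sum|p|^2 = 1 for the ideal pupil."""
    g = _grids(pupil.optics)
    u = _pupil_u(pupil, x, y, z)
    p = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(u, axes=(-2, -1))),
                        axes=(-2, -1))
    return p / g.norm


def _blur_filter(pupil: PupilModel) -> np.ndarray | None:
    if pupil.blur_sigma == 0.0:
        return None
    g = _grids(pupil.optics)
    return np.exp(-2.0 * np.pi ** 2 * pupil.blur_sigma ** 2 * g.f2)


def _apply_blur(img: np.ndarray, filt: np.ndarray | None) -> np.ndarray:
    if filt is None:
        return img
    return np.fft.ifft2(np.fft.fft2(img) * filt).real


def psf_theoretical(pupil: PupilModel, x: float, y: float, z) -> np.ndarray:
    """Diffraction-limited PSF image(s) |F(pupil field)|^2, no blur.

    ``x, y, z`` are the emitter position in nm; ``z`` may be an array, in
    which case a stack is returned.  Images are on the ``fft_size`` grid with
    the emitter at the geometric center for x = y = 0.
    """
    p = _pupil_field(pupil, x, y, z)
    return (p.real ** 2 + p.imag ** 2)


def psf_model(pupil: PupilModel, x: float, y: float, z,
              window: int | None = None) -> np.ndarray:
    """Blurred PSF (the fitting model): psf_theoretical * Gaussian(blur_sigma).

    The blur acts on the periodic FFT grid, which preserves total intensity
    exactly.  If ``window`` is given the central window x window region is
    returned.
    """
    img = _apply_blur(psf_theoretical(pupil, x, y, z), _blur_filter(pupil))
    if window is not None:
        img = crop_center(img, window)
    return img


_POS_FACTORS = ("x", "y", "z")


def psf_and_derivatives(pupil: PupilModel, x: float, y: float, z,
                        wrt: Sequence[str] = ("x", "y", "z"),
                        window: int | None = None,
                        ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """PSF and analytic partial derivatives.

    ``wrt`` may contain ``'x'``, ``'y'``, ``'z'`` (nm), ``'sigma'`` (pixels)
    and ``'c<j>'`` for Zernike coefficients (radians), e.g. ``'c5'``.
    Derivatives propagate exactly through the Gaussian blur (the blur is
    linear).  Returns ``(psf, {name: dpsf})``, each cropped to ``window``.
    """
    g = _grids(pupil.optics)
    u = _pupil_u(pupil, x, y, z)
    p = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(u, axes=(-2, -1))),
                        axes=(-2, -1)) / g.norm
    psf = p.real ** 2 + p.imag ** 2
    filt = _blur_filter(pupil)
    derivs: dict[str, np.ndarray] = {}
    for name in wrt:
        if name == "sigma":
            continue
        if name == "x":
            fac = 2j * np.pi * g.kx
        elif name == "y":
            fac = 2j * np.pi * g.ky
        elif name == "z":
            fac = 2j * np.pi * g.kz2
        elif name.startswith("c"):
            fac = 1j * g.zernike(int(name[1:]))
        else:
            raise ValueError(f"unknown derivative target {name!r}")
        # d|p|^2 = 2 Re(conj(p) dp) with dp = F(fac * u)
        dp = np.fft.fftshift(
            np.fft.fft2(np.fft.ifftshift(fac * u, axes=(-2, -1))),
            axes=(-2, -1)) / g.norm
        derivs[name] = 2.0 * (p.real * dp.real + p.imag * dp.imag)
    psf_b = _apply_blur(psf, filt)
    out = {k: _apply_blur(v, filt) for k, v in derivs.items()}
    if "sigma" in wrt:
        if filt is None:
            # at sigma == 0 use the one-sided analytic limit through the
            # Fourier filter derivative (which is 0 there)
            out["sigma"] = np.zeros_like(psf)
        else:
            dfilt = -4.0 * np.pi ** 2 * pupil.blur_sigma * g.f2 * filt
            out["sigma"] = np.fft.ifft2(np.fft.fft2(psf) * dfilt).real
    if window is not None:
        psf_b = crop_center(psf_b, window)
        out = {k: crop_center(v, window) for k, v in out.items()}
    return psf_b, out


def _pupil_u(pupil: PupilModel, x, y, z) -> np.ndarray:
    """The (centered) pupil-plane field before Fourier transform."""
    g = _grids(pupil.optics)
    z = np.asarray(z, dtype=float)
    phi = phase_from_coeffs(pupil)
    f = pupil.optics.focal_offset
    phase = phi + 2.0 * np.pi * (x * g.kx + y * g.ky - f * g.kz1)
    phase = phase + 2.0 * np.pi * z[..., None, None] * g.kz2
    return g.amplitude * np.exp(1j * phase)


def crop_center(img: np.ndarray, window: int) -> np.ndarray:
    """Central odd ``window x window`` crop of the last two axes."""
    n = img.shape[-1]
    if window % 2 == 0 or window > n:
        raise ValueError("window must be odd and <= grid size")
    c = n // 2
    h = window // 2
    return img[..., c - h:c + h + 1, c - h:c + h + 1]
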