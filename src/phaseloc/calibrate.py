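"""PSF calibration by phase retrieval: Poisson MLE of the pupil state.

The full parameter vector couples the optical state (Zernike coefficients
c_4..c_J and the Gaussian blur sigma) with per-bead nuisance parameters
(per-plane amplitudes A_{s,k}, six background polynomial coefficients, and
the 3D bead offset).  All are estimated jointly from one or more bead
z-stacks by minimizing the Poisson negative log likelihood, iterating
safeguarded coordinate-wise Newton updates: geometry first (it stabilizes
photometry), then amplitudes, background, Zernike coefficients and blur.

Curvatures use Fisher scoring (the expected, always-positive Hessian
diagonal) for parameters entering through the PSF, and exact second
derivatives for the linear amplitude/background parameters; every grouped
update is accepted only if it does not increase the NLL (backtracking by
step halving, reverting on failure), which makes the per-iteration NLL
sequence non-increasing by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .camera import (MODEL_FLOOR, BeadStackSet, CalibrationParams,
                     background_basis)
from .optics import OpticsConfig, PupilModel, psf_and_derivatives, psf_model

__all__ = ["RetrievalConfig", "initialize_params", "retrieve"]

log = logging.getLogger(__name__)


@dataclass
class RetrievalConfig:
    """Knobs of the phase-retrieval optimizer.

    ``j_max`` Zernike truncation (Noll index), ``n_iterations`` outer
    iterations, ``fit_blur_sigma`` whether sigma is estimated, ``damping``
    step-halving factor used during backtracking.
    """

    j_max: int = 36
    n_iterations: int = 30
    fit_blur_sigma: bool = True
    damping: float = 0.5
    init_blur_sigma: float = 0.5
    rel_tol: float = 1e-6
    max_backtracks: int = 8
    coeff_step_max: float = 0.25    # rad per iteration per coefficient
    axial_step_max: float = 100.0   # nm
    sigma_bounds: tuple[float, float] = (0.0, 3.0)

    def __post_init__(self) -> None:
        if self.j_max < 4:
            raise ValueError("j_max must be >= 4")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def initialize_params(beads: BeadStackSet, config: RetrievalConfig | None = None,
                      optics=None) -> CalibrationParams:
    """Moment-based starting point: zero phase, centroid offsets, flat
    background from border pixels, amplitudes from plane sums."""
    config = config or RetrievalConfig()
    optics = optics or OpticsConfig()
    w = beads.window
    p = optics.pixel_size
    amps, bgs, offs = [], [], []
    for stack in beads.stacks:
        border = np.concatenate([stack[:, 0, :].ravel(), stack[:, -1, :].ravel(),
                                 stack[:, :, 0].ravel(), stack[:, :, -1].ravel()])
        b5 = float(np.median(border))
        signal = np.clip(stack - b5, 0.0, None)
        if signal.max() <= 5.0 * np.sqrt(b5 + 1.0):
            raise ValueError("stack shows no bead signal above background")
        kc = beads.n_planes // 2
        plane = signal[kc]
        tot = plane.sum()
        if tot <= 0:
            raise ValueError("central plane is empty")
        rows, cols = np.indices(plane.shape)
        cy = float((rows * plane).sum() / tot)
        cx = float((cols * plane).sum() / tot)
        dx = (cx - w // 2) * p
        dy = (cy - w // 2) * p
        # focus: plane with the sharpest (smoothed) peak; for strongly
        # engineered PSFs this can land on a line focus several planes from
        # the true focus, which `retrieve` guards against with pilot runs
        sharp = gaussian_filter(signal, sigma=(0, 1, 1)).max(axis=(1, 2))
        dz = -float(beads.z_planes[int(np.argmax(sharp))])
        a = np.clip(signal.sum(axis=(1, 2)), 1.0, None)
        amps.append(a)
        bgs.append(np.array([0, 0, 0, 0, 0, b5], dtype=float))
        offs.append(np.array([dx, dy, dz]))
    pupil = PupilModel(optics=optics, coeffs=np.zeros(config.j_max - 3),
                       blur_sigma=config.init_blur_sigma if config.fit_blur_sigma
                       else 0.7)
    return CalibrationParams(pupil=pupil, amplitudes=amps, backgrounds=bgs,
                             offsets=offs)


class _Fit:
    """Mutable optimizer state for one retrieval run."""

    def __init__(self, beads: BeadStackSet, params: CalibrationParams,
                 config: RetrievalConfig) -> None:
        self.beads = beads
        self.config = config
        self.w = beads.window
        v = beads.camera.variance_offset()
        self.v = v
        self.data = [np.asarray(s, float) + v for s in beads.stacks]
        self.basis = background_basis(self.w)
        self.pupil = params.pupil
        self.amps = [a.copy() for a in params.amplitudes]
        self.bgs = [b.copy() for b in params.backgrounds]
        self.offs = [o.copy() for o in params.offsets]
        self.n_clamped = 0
        self.psfs = [self._psf(s) for s in range(beads.n_beads)]

    # -- model pieces -----------------------------------------------------
    def _psf(self, s: int) -> np.ndarray:
        dx, dy, dz = self.offs[s]
        return psf_model(self.pupil, dx, dy, self.beads.z_planes + dz,
                         window=self.w)

    def _bg_map(self, s: int) -> np.ndarray:
        return np.tensordot(self.bgs[s], self.basis, axes=1)

    def model(self, s: int, psf=None, a=None, bg=None) -> np.ndarray:
        psf = self.psfs[s] if psf is None else psf
        a = self.amps[s] if a is None else a
        bg = self._bg_map(s) if bg is None else bg
        m = a[:, None, None] * psf + bg[None, :, :] + self.v
        n_bad = int(np.count_nonzero(m < MODEL_FLOOR))
        self.n_clamped += n_bad
        return np.maximum(m, MODEL_FLOOR)

    def nll_bead(self, s: int, model=None) -> float:
        m = self.model(s) if model is None else model
        return float(np.sum(m - self.data[s] * np.log(m)))

    def nll(self) -> float:
        return sum(self.nll_bead(s) for s in range(self.beads.n_beads))

    # -- safeguarded update groups ---------------------------------------
    def _backtrack(self, s: int, nll0: float, trial_model):
        """Try full step, halving until the bead NLL does not increase.

        ``trial_model(scale)`` returns the bead model for a scaled step.
        Returns the accepted scale (0.0 means reverted)."""
        scale = 1.0
        for _ in range(self.config.max_backtracks):
            m = trial_model(scale)
            if self.nll_bead(s, m) <= nll0 + 1e-12 * abs(nll0):
                return scale
            scale *= self.config.damping
        return 0.0

    def geometry_step(self, s: int) -> None:
        dx, dy, dz = self.offs[s]
        psf, d = psf_and_derivatives(self.pupil, dx, dy,
                                     self.beads.z_planes + dz,
                                     wrt=("x", "y", "z"), window=self.w)
        self.psfs[s] = psf
        m = self.model(s)
        resid = 1.0 - self.data[s] / m
        a3 = self.amps[s][:, None, None]
        step = np.zeros(3)
        p = self.pupil.optics.pixel_size
        clamps = (0.5 * p, 0.5 * p, self.config.axial_step_max)
        for q, name in enumerate(("x", "y", "z")):
            dm = a3 * d[name]
            g = float(np.sum(resid * dm))
            h = float(np.sum(dm * dm / m))
            if h > 0:
                step[q] = np.clip(-g / h, -clamps[q], clamps[q])
        nll0 = self.nll_bead(s, m)

        def trial(scale):
            o = self.offs[s] + scale * step
            psf_t = psf_model(self.pupil, o[0], o[1],
                              self.beads.z_planes + o[2], window=self.w)
            trial.psf = psf_t
            return self.model(s, psf=psf_t)

        scale = self._backtrack(s, nll0, trial)
        if scale > 0:
            self.offs[s] = self.offs[s] + scale * step
            self.psfs[s] = trial.psf

    def amplitude_step(self, s: int) -> None:
        psf = self.psfs[s]
        m = self.model(s)
        resid = 1.0 - self.data[s] / m
        g = np.sum(psf * resid, axis=(1, 2))
        h = np.sum(self.data[s] * psf ** 2 / m ** 2, axis=(1, 2))
        step = np.where(h > 0, -g / np.maximum(h, 1e-300), 0.0)
        nll0 = self.nll_bead(s, m)

        def trial(scale):
            a = np.clip(self.amps[s] + scale * step, 0.0, None)
            trial.a = a
            return self.model(s, a=a)

        scale = self._backtrack(s, nll0, trial)
        if scale > 0:
            self.amps[s] = trial.a

    def background_step(self, s: int) -> None:
        m = self.model(s)
        resid = 1.0 - self.data[s] / m
        step = np.zeros(6)
        for q in range(6):
            x = self.basis[q][None, :, :]
            g = float(np.sum(resid * x))
            h = float(np.sum(self.data[s] * x ** 2 / m ** 2))
            if h > 0:
                step[q] = -g / h
        nll0 = self.nll_bead(s, m)

        def trial(scale):
            b = self.bgs[s] + scale * step
            trial.b = b
            return self.model(s, bg=np.tensordot(b, self.basis, axes=1))

        scale = self._backtrack(s, nll0, trial)
        if scale > 0:
            self.bgs[s] = trial.b

    def _global_step(self, wrt: Sequence[str], apply, clamp: float,
                     extra_bounds=None) -> None:
        """Joint safeguarded Newton step over pupil parameters ``wrt``."""
        g = np.zeros(len(wrt))
        h = np.zeros(len(wrt))
        nll0 = 0.0
        for s in range(self.beads.n_beads):
            dx, dy, dz = self.offs[s]
            psf, d = psf_and_derivatives(self.pupil, dx, dy,
                                         self.beads.z_planes + dz,
                                         wrt=wrt, window=self.w)
            self.psfs[s] = psf
            m = self.model(s)
            resid = 1.0 - self.data[s] / m
            a3 = self.amps[s][:, None, None]
            for q, name in enumerate(wrt):
                dm = a3 * d[name]
                g[q] += np.sum(resid * dm)
                h[q] += np.sum(dm * dm / m)
            nll0 += self.nll_bead(s, m)
        step = np.where(h > 0, -g / np.maximum(h, 1e-300), 0.0)
        step = np.clip(step, -clamp, clamp)
        old_pupil = self.pupil
        scale = 1.0
        for _ in range(self.config.max_backtracks):
            trial_pupil = apply(old_pupil, scale * step)
            if extra_bounds is not None and not extra_bounds(trial_pupil):
                scale *= self.config.damping
                continue
            self.pupil = trial_pupil
            psfs = [self._psf(s) for s in range(self.beads.n_beads)]
            nll1 = sum(self.nll_bead(s, self.model(s, psf=psfs[s]))
                       for s in range(self.beads.n_beads))
            if nll1 <= nll0 + 1e-12 * abs(nll0):
                self.psfs = psfs
                return
            scale *= self.config.damping
        self.pupil = old_pupil
        self.psfs = [self._psf(s) for s in range(self.beads.n_beads)]

    def coeff_step(self) -> None:
        names = [f"c{j}" for j in range(4, self.config.j_max + 1)]

        def apply(pupil, step):
            return pupil.with_coeffs(pupil.coeffs + step)

        self._global_step(names, apply, self.config.coeff_step_max)

    def sigma_step(self) -> None:
        lo, hi = self.config.sigma_bounds

        def apply(pupil, step):
            from dataclasses import replace
            return replace(pupil,
                           blur_sigma=float(np.clip(pupil.blur_sigma + step[0],
                                                    lo, hi)))

        self._global_step(["sigma"], apply, 0.25)

    def to_params(self) -> CalibrationParams:
        return CalibrationParams(pupil=self.pupil, amplitudes=self.amps,
                                 backgrounds=self.bgs, offsets=self.offs)


def _iterate(fit: _Fit, n_iterations: int, history: list[float]) -> None:
    """Run outer coordinate-descent iterations, appending NLL values."""
    config = fit.config
    beads = fit.beads
    for _ in range(n_iterations):
        for s in range(beads.n_beads):
            fit.geometry_step(s)
            fit.amplitude_step(s)
            fit.background_step(s)
        fit.coeff_step()
        if config.fit_blur_sigma:
            fit.sigma_step()
        nll = fit.nll()
        history.append(nll)
        if history[-2] - nll < config.rel_tol * abs(nll):
            break


def retrieve(beads: BeadStackSet, config: RetrievalConfig | None = None,
             init: CalibrationParams | None = None,
             ) -> tuple[CalibrationParams, dict]:
    """Estimate the full calibration parameter vector from bead z-stacks.

    When no ``init`` is supplied, a moment-based start is built and short
    pilot runs are launched from a few candidate axial offsets (sharpest
    plane and mid-stack): for strongly astigmatic or tetrapod-like pupils
    the sharpest plane is a line focus, and descending from it lands in a
    local minimum.  The pilot with the lowest NLL is continued to the full
    iteration count.

    Returns ``(params, report)``; the report carries the per-iteration NLL
    (non-increasing), per-plane reduced chi-square of the final fit, and the
    count of model pixels clamped at the positivity floor.
    """
    config = config or RetrievalConfig()
    explicit_init = init is not None
    if init is None:
        init = initialize_params(beads, config)
    if init.pupil.coeffs.size != config.j_max - 3:
        raise ValueError("init pupil j_max inconsistent with config.j_max")
    fit = _Fit(beads, init, config)
    nll0 = fit.nll()
    if not np.isfinite(nll0):
        raise ValueError("non-finite NLL at the initial parameters")
    history = [nll0]
    if explicit_init:
        _iterate(fit, config.n_iterations, history)
    else:
        z = beads.z_planes
        dz_mid = -float(0.5 * (z[0] + z[-1]))
        candidates = [[o.copy() for o in init.offsets]]
        if any(abs(o[2] - dz_mid) > (z[1] - z[0]) for o in init.offsets):
            candidates.append([np.array([o[0], o[1], dz_mid])
                               for o in init.offsets])
        if len(candidates) == 1:
            _iterate(fit, config.n_iterations, history)
        else:
            n_pilot = max(4, config.n_iterations // 5)
            best = None
            for offs in candidates:
                cand = CalibrationParams(
                    pupil=init.pupil, amplitudes=init.amplitudes,
                    backgrounds=init.backgrounds, offsets=offs)
                f = _Fit(beads, cand, config)
                h = [f.nll()]
                _iterate(f, n_pilot, h)
                if best is None or h[-1] < best[1][-1]:
                    best = (f, h)
            fit, history = best
            _iterate(fit, config.n_iterations - n_pilot, history)
    params = fit.to_params()
    # per-plane reduced chi2 of the final model, pooled over beads
    chi2 = np.zeros(beads.n_planes)
    npix = 0
    for s in range(beads.n_beads):
        m = fit.model(s)
        chi2 += np.sum((fit.data[s] - m) ** 2 / m, axis=(1, 2))
        npix += fit.w ** 2
    report = {
        "nll_history": np.asarray(history),
        "chi2_per_plane": chi2 / npix,
        "n_clamped": fit.n_clamped,
        "n_iterations": len(history) - 1,
    }
    return params, report
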