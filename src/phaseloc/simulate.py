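"""Ground-truth simulators: bead calibration stacks, repeated-bead precision
runs, drifting localization sets and sparse blinking single-molecule movies.

All generators draw Poisson pixel noise from the same image-formation model
used for fitting, are deterministic under a fixed seed, and return the exact
ground truth alongside the data.  Defaults mirror a typical engineered-PSF
acquisition: a 40-plane bead stack stepped by 100 nm over 4 um, and
repeated-bead runs of 50 frames per axial position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .camera import BeadStackSet, CameraModel, background_poly, window_coords
from .optics import PupilModel, psf_model

__all__ = [
    "GroundTruth",
    "simulate_bead_stack",
    "simulate_repeat_bead",
    "simulate_movie",
    "simulate_drifted_records",
    "add_molecule",
]


@dataclass
class GroundTruth:
    """Exact generating parameters of a simulation."""

    molecules: pd.DataFrame   # one row per emission: frame, x, y, z, photons
    background: float
    pupil: PupilModel
    seed: int
    extras: dict = field(default_factory=dict)


def add_molecule(frame: np.ndarray, pupil: PupilModel, x: float, y: float,
                 z: float, photons: float, window: int | None = None) -> None:
    """Add ``photons * PSF(x, y, z)`` into ``frame`` in place.

    ``(x, y)`` are nm relative to the top-left pixel center (x along
    columns).  The PSF window is centered on the nearest pixel with the
    residual subpixel offset folded into the model evaluation.
    """
    p = pupil.optics.pixel_size
    n = pupil.optics.fft_size
    w = window if window is not None else n - 1
    if w % 2 == 0:
        w -= 1
    px = int(round(x / p))
    py = int(round(y / p))
    sub_x = x - px * p
    sub_y = y - py * p
    psf = psf_model(pupil, sub_x, sub_y, z, window=w)
    h = w // 2
    r0, r1 = py - h, py + h + 1
    c0, c1 = px - h, px + h + 1
    tr0, tc0 = max(r0, 0), max(c0, 0)
    tr1, tc1 = min(r1, frame.shape[0]), min(c1, frame.shape[1])
    if tr1 <= tr0 or tc1 <= tc0:
        return
    frame[tr0:tr1, tc0:tc1] += photons * psf[tr0 - r0:tr1 - r0, tc0 - c0:tc1 - c0]


def simulate_bead_stack(pupil: PupilModel, z_start: float = -2000.0,
                        z_step: float = 100.0, n_planes: int = 40,
                        photons_per_plane: float = 4000.0,
                        background: float = 10.0, bleach_rate: float = 0.0,
                        window: int = 31, offsets=(0.0, 0.0, 0.0),
                        background_coeffs=None,
                        camera: CameraModel | None = None,
                        seed: int = 0) -> tuple[BeadStackSet, GroundTruth]:
    """One synthetic calibration bead z-stack with Poisson noise.

    Per-plane amplitudes decay as ``photons * exp(-bleach_rate * k)`` to
    emulate photobleaching during stack acquisition.  Returns the stack in
    photon units together with the exact generating truth.
    """
    if n_planes < 2:
        raise ValueError("need at least 2 planes")
    rng = np.random.default_rng(seed)
    z_planes = z_start + z_step * np.arange(n_planes)
    amps = photons_per_plane * np.exp(-bleach_rate * np.arange(n_planes))
    dx, dy, dz = offsets
    psf = psf_model(pupil, dx, dy, z_planes + dz, window=window)
    if background_coeffs is None:
        background_coeffs = np.array([0, 0, 0, 0, 0, float(background)])
    x, y = window_coords(window)
    bg = background_poly(background_coeffs, x, y)
    mean = amps[:, None, None] * psf + bg[None, :, :]
    stack = rng.poisson(np.clip(mean, 0, None)).astype(float)
    camera = camera or CameraModel()
    beads = BeadStackSet(stacks=[stack], z_planes=z_planes, camera=camera)
    truth = GroundTruth(
        molecules=pd.DataFrame({"frame": np.arange(n_planes),
                                "x": dx, "y": dy, "z": z_planes + dz,
                                "photons": amps}),
        background=float(background), pupil=pupil, seed=seed,
        extras={"amplitudes": amps, "offsets": np.asarray(offsets, float),
                "background_coeffs": np.asarray(background_coeffs, float)})
    return beads, truth


def simulate_repeat_bead(pupil: PupilModel, z_list=None, n_repeats: int = 50,
                         photons: float = 4677.0, background: float = 18.2,
                         window: int = 31, seed: int = 0,
                         ) -> tuple[np.ndarray, GroundTruth]:
    """Repeated noisy frames of a fixed bead at each axial position.

    Defaults follow a precision-vs-CRLB validation run: 50 frames at each of
    40 positions stepped by 100 nm over 4 um.  Returns frames of shape
    ``(len(z_list) * n_repeats, window, window)`` and the per-frame truth.
    """
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    if z_list is None:
        z_list = -2000.0 + 100.0 * np.arange(40)
    z_list = np.asarray(z_list, dtype=float)
    rng = np.random.default_rng(seed)
    psf = psf_model(pupil, 0.0, 0.0, z_list, window=window)
    mean = photons * psf + background
    frames = rng.poisson(np.repeat(mean, n_repeats, axis=0)).astype(float)
    half = window // 2
    p = pupil.optics.pixel_size
    truth = GroundTruth(
        molecules=pd.DataFrame({
            "frame": np.arange(frames.shape[0]),
            "x": half * p, "y": half * p,
            "z": np.repeat(z_list, n_repeats),
            "photons": photons}),
        background=float(background), pupil=pupil, seed=seed,
        extras={"z_list": z_list, "n_repeats": n_repeats})
    return frames, truth


def simulate_movie(pupil: PupilModel, n_frames: int = 100,
                   molecules_per_frame: float = 1.0,
                   photons_median: float = 3000.0, photons_sigma_log: float = 0.5,
                   background: float = 20.0, frame_size: int = 64,
                   z_range: tuple[float, float] = (-1000.0, 1000.0),
                   mean_on_frames: float = 2.0, window: int = 25,
                   drift_fn: Callable[[int], tuple[float, float, float]] | None = None,
                   seed: int = 0) -> tuple[np.ndarray, GroundTruth]:
    """Sparse blinking single-molecule movie with Poisson noise.

    Emitters activate at a Poisson rate, stay on for a geometric number of
    frames (mean ``mean_on_frames``) at a fixed true position, and emit a
    log-normal photon count each frame.  Active emitters are kept laterally
    separated by at least 1.5 fitting windows: the localizer is a
    single-emitter fit by contract, so overlapping PSFs are out of scope.
    ``drift_fn(frame) -> (dx, dy, dz)`` nm displaces true positions.

    Returns ``(frames, truth)`` where the truth table has one row per
    emission (frame, x, y, z include drift, photons) plus molecule ids.
    """
    rng = np.random.default_rng(seed)
    p = pupil.optics.pixel_size
    min_sep = 1.5 * window * p
    margin = (window // 2 + 1) * p
    lo, hi = margin, (frame_size - 1) * p - margin
    if hi <= lo:
        raise ValueError("frame too small for the fitting window")
    area_capacity = max(1, int(((hi - lo) / min_sep + 1) ** 2))
    # steady-state active emitter count is molecules_per_frame
    if molecules_per_frame > 0.5 * area_capacity:
        raise ValueError(
            f"density infeasible for non-overlapping emitters; at most "
            f"{0.5 * area_capacity:.2f} simultaneously active emitters fit")

    frames = np.zeros((n_frames, frame_size, frame_size))
    active: list[dict] = []
    rows = []
    mol_id = 0
    p_off = 1.0 / max(mean_on_frames, 1.0)
    for t in range(n_frames):
        active = [m for m in active if rng.random() >= p_off]
        # activation rate chosen so the steady-state active count is
        # molecules_per_frame (birth rate x mean lifetime)
        rate = molecules_per_frame / max(mean_on_frames, 1.0)
        n_new = rng.poisson(rate) if rate > 0 else 0
        for _ in range(n_new):
            for _attempt in range(50):
                x = rng.uniform(lo, hi)
                y = rng.uniform(lo, hi)
                if all((x - m["x"]) ** 2 + (y - m["y"]) ** 2 >= min_sep ** 2
                       for m in active):
                    break
            else:
                continue
            z = rng.uniform(*z_range)
            mol_id += 1
            active.append({"id": mol_id, "x": x, "y": y, "z": z})
        ddx = ddy = ddz = 0.0
        if drift_fn is not None:
            ddx, ddy, ddz = drift_fn(t)
        img = frames[t]
        for m in active:
            photons = float(np.exp(np.log(photons_median)
                                   + photons_sigma_log * rng.standard_normal()))
            xd, yd, zd = m["x"] + ddx, m["y"] + ddy, m["z"] + ddz
            add_molecule(img, pupil, xd, yd, zd, photons, window=window)
            rows.append({"frame": t, "id": m["id"], "x": xd, "y": yd,
                         "z": zd, "photons": photons})
        frames[t] = rng.poisson(np.clip(img + background, 0, None))
    truth_df = pd.DataFrame(rows, columns=["frame", "id", "x", "y", "z",
                                           "photons"])
    truth = GroundTruth(molecules=truth_df, background=float(background),
                        pupil=pupil, seed=seed,
                        extras={"drift_fn": drift_fn, "window": window})
    return frames, truth


def simulate_drifted_records(n_frames: int = 50000, locs_per_frame: float = 5.0,
                             structure: np.ndarray | None = None,
                             loc_sigma: tuple[float, float, float] = (10.0, 10.0, 20.0),
                             drift_fn: Callable[[np.ndarray], np.ndarray] | None = None,
                             seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Localization table of a rigid structure under drift (records level).

    A cheap stand-in for rendering and re-fitting tens of thousands of
    movie frames: localizations are sampled directly as structure points
    plus Gaussian localization error, then displaced by the injected drift.
    ``structure`` is an (n_points, 3) array in nm (default: a 3D ring of
    2 um diameter).  ``drift_fn(frames) -> (n, 3)`` returns drift in nm.

    Returns ``(records, true_drift)`` with ``true_drift`` of shape
    ``(n_frames, 3)``.
    """
    rng = np.random.default_rng(seed)
    if structure is None:
        t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        structure = np.column_stack([
            2000 + 1000 * np.cos(t), 2000 + 1000 * np.sin(t),
            600 + 300 * np.sin(2 * t)])
    n_locs = rng.poisson(locs_per_frame, size=n_frames)
    frames = np.repeat(np.arange(n_frames), n_locs)
    idx = rng.integers(0, len(structure), size=frames.size)
    pos = structure[idx] + rng.standard_normal((frames.size, 3)) * np.asarray(loc_sigma)
    if drift_fn is None:
        true_drift = np.zeros((n_frames, 3))
    else:
        true_drift = np.asarray(drift_fn(np.arange(n_frames)), dtype=float)
    pos = pos + true_drift[frames]
    records = pd.DataFrame({
        "frame": frames, "x_nm": pos[:, 0], "y_nm": pos[:, 1],
        "z_nm": pos[:, 2], "photons": 3000.0, "background": 20.0,
        "chi2": 1.0, "crlb_x_nm": loc_sigma[0], "crlb_y_nm": loc_sigma[1],
        "crlb_z_nm": loc_sigma[2], "score": 1.0, "n_merged": 1})
    return records, true_drift
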