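"""Simulation studies validating the pipeline end to end.

Each function runs one self-contained study at desk scale — generating its
inputs with the `simulate` module, running the estimator under test, and
measuring the result against the generator's ground truth.  They are used
by the test suite and by ``scripts/acceptance.py``; all randomness is
controlled by an explicit seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibrate import RetrievalConfig, retrieve
from .detect import build_templates, detect
from .localize import chi2, refine
from .optics import OpticsConfig, PupilModel, psf_model
from .postprocess import DriftConfig, estimate_drift
from .precision import OptimizationSpec, crlb_curve, fisher_matrix, optimize_psf
from .simulate import (simulate_bead_stack, simulate_drifted_records,
                       simulate_repeat_bead)

__all__ = [
    "precision_vs_crlb_study",
    "coefficient_recovery_study",
    "fisher_consistency_study",
    "chi2_null_study",
    "drift_recovery_study",
    "psf_design_study",
]


def _saddle_pupil(fft_size: int = 64) -> PupilModel:
    coeffs = np.zeros(12)
    coeffs[11 - 4] = 2.0  # spherical term: saddle-point-like, ~4 um range
    return PupilModel(optics=OpticsConfig(fft_size=fft_size), coeffs=coeffs,
                      blur_sigma=0.7)


def precision_vs_crlb_study(seed: int = 1, n_repeats: int = 50,
                            n_z: int = 9, z_span: float = 2000.0,
                            photons: float = 4677.0, background: float = 18.2,
                            ) -> pd.DataFrame:
    """Repeated-bead localization precision against the CRLB.

    Repeated noisy frames of a fixed emitter are taken at each of ``n_z``
    axial positions spanning ±``z_span`` with a saddle-point-like PSF at
    the bead-run photometry, each frame is detected and refined, and the
    per-z empirical standard deviation of (x, y, z) estimates is compared
    with the mean reported per-record CRLB.

    Returns one row per (z, axis) with columns z_nm, axis, emp_std_nm,
    mean_crlb_nm, ratio.
    """
    pupil = _saddle_pupil()
    z_list = np.linspace(-z_span, z_span, n_z)
    frames, truth = simulate_repeat_bead(pupil, z_list=z_list,
                                         n_repeats=n_repeats,
                                         photons=photons,
                                         background=background, window=31,
                                         seed=seed)
    templates = build_templates(pupil, -z_span - 200.0, z_span + 200.0,
                                window=25)
    fits: dict[float, list] = {z: [] for z in z_list}
    z_true = truth.molecules["z"].to_numpy()
    for i in range(frames.shape[0]):
        cands = detect(frames[i], templates)
        if not cands:
            continue
        rec = refine(frames[i], cands[0], pupil, templates)
        if rec is None:
            continue
        fits[z_true[i]].append([rec.x, rec.y, rec.z, rec.crlb_x, rec.crlb_y,
                                rec.crlb_z])
    rows = []
    for z in z_list:
        arr = np.asarray(fits[z])
        std = arr[:, :3].std(axis=0, ddof=1)
        mean_crlb = arr[:, 3:].mean(axis=0)
        for ax, name in enumerate("xyz"):
            rows.append({"z_nm": z, "axis": name, "n": len(arr),
                         "emp_std_nm": std[ax],
                         "mean_crlb_nm": mean_crlb[ax],
                         "ratio": std[ax] / mean_crlb[ax]})
    return pd.DataFrame(rows)


def coefficient_recovery_study(seed: int = 1, n_trials: int = 10,
                               photons_per_plane: float = 4000.0,
                               coeff_range: float = 1.5) -> pd.DataFrame:
    """Phase-retrieval accuracy on known low-order aberrations.

    For each trial, Zernike coefficients c5, c6, c7, c8 and c11 are drawn
    uniformly in ±``coeff_range`` rad, a single 40-plane bead stack is
    simulated and the pupil re-estimated from scratch.  Returns one row per
    (trial, index) with the signed estimation error in radians.
    """
    rng = np.random.default_rng(seed)
    optics = OpticsConfig(fft_size=64)
    indices = (5, 6, 7, 8, 11)
    rows = []
    config = RetrievalConfig(j_max=15, n_iterations=30, fit_blur_sigma=True)
    for trial in range(n_trials):
        coeffs = np.zeros(12)
        for j in indices:
            coeffs[j - 4] = rng.uniform(-coeff_range, coeff_range)
        truth_pupil = PupilModel(optics=optics, coeffs=coeffs, blur_sigma=0.0)
        beads, _ = simulate_bead_stack(
            truth_pupil, photons_per_plane=photons_per_plane,
            background=10.0, window=31,
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        params, _ = retrieve(beads, config)
        for j in indices:
            rows.append({"trial": trial, "noll_index": j,
                         "true_rad": coeffs[j - 4],
                         "error_rad": params.pupil.coeffs[j - 4]
                         - coeffs[j - 4]})
    return pd.DataFrame(rows)


def fisher_consistency_study(seed: int = 1, n_pupils: int = 20,
                             window: int = 21, fd_step: float = 0.1) -> float:
    """Worst relative deviation between the analytic Fisher matrix and a
    central-finite-difference construction, over random pupils."""
    rng = np.random.default_rng(seed)
    optics = OpticsConfig(fft_size=64)
    worst = 0.0
    for _ in range(n_pupils):
        pupil = PupilModel(optics=optics, coeffs=rng.uniform(-1, 1, 12),
                           blur_sigma=0.7)
        a_ph, b_ph = 3000.0, 20.0
        z = float(rng.uniform(-800, 800))
        analytic = fisher_matrix(pupil, a_ph, b_ph, z=z, window=window)

        def model(xx, yy, zz, aa, bb):
            return aa * psf_model(pupil, xx, yy, zz, window=window) + bb

        m0 = model(0, 0, z, a_ph, b_ph)
        dm = []
        for delta, h in zip([(fd_step, 0, 0, 0, 0), (0, fd_step, 0, 0, 0),
                             (0, 0, fd_step, 0, 0), (0, 0, 0, 1.0, 0),
                             (0, 0, 0, 0, 1.0)],
                            [fd_step, fd_step, fd_step, 1.0, 1.0]):
            hi = model(delta[0], delta[1], z + delta[2], a_ph + delta[3],
                       b_ph + delta[4])
            lo = model(-delta[0], -delta[1], z - delta[2], a_ph - delta[3],
                       b_ph - delta[4])
            dm.append((hi - lo) / (2 * h))
        fd = np.array([[np.sum(dm[u] * dm[v] / m0) for v in range(5)]
                       for u in range(5)])
        worst = max(worst, float(np.abs(analytic - fd).max()
                                 / np.abs(fd).max()))
    return worst


def chi2_null_study(seed: int = 1, n_windows: int = 500, window: int = 15,
                    mean: float = 50.0) -> float:
    """Mean reduced chi-square of pure-Poisson windows against their model."""
    rng = np.random.default_rng(seed)
    model = np.full((window, window), mean)
    vals = [chi2(rng.poisson(model).astype(float), model)
            for _ in range(n_windows)]
    return float(np.mean(vals))


def drift_recovery_study(seed: int = 1, n_frames: int = 20000,
                         n_windows: int = 20, amplitude: float = 300.0,
                         voxel: float = 30.0) -> dict:
    """Injected linear + sinusoidal 3D drift recovered from localizations.

    Returns per-axis RMSE (nm) between estimated and injected per-frame
    drift, mean-aligned (the absolute offset is unobservable).
    """
    def drift_fn(frames):
        t = frames / n_frames
        return np.column_stack([
            amplitude * t + 0.3 * amplitude * np.sin(4 * np.pi * t),
            -0.5 * amplitude * t,
            0.7 * amplitude * t + 0.25 * amplitude * np.sin(6 * np.pi * t)])

    records, true_drift = simulate_drifted_records(
        n_frames=n_frames, locs_per_frame=5.0, drift_fn=drift_fn, seed=seed)
    config = DriftConfig(window_frames=n_frames // n_windows, voxel=voxel,
                         max_drift=3 * amplitude)
    trace = estimate_drift(records, config)
    out = {}
    for d, name in enumerate("xyz"):
        diff = trace.per_frame[:, d] - true_drift[:, d]
        diff -= diff.mean()
        out[f"rmse_{name}_nm"] = float(np.sqrt(np.mean(diff ** 2)))
    return out


def psf_design_study(seed: int = 1, n_starts: int = 5,
                     n_iterations: int = 15, window: int = 41) -> dict:
    """Range/resolution trade-off of CRLB-optimized PSFs.

    Optimizes pupils for 1 um and 3 um axial ranges and evaluates both on
    the mean axial CRLB over ±1.5 um: the 3 um design must win on its own
    range.  Also reports the per-iteration objective history of each
    optimization (non-increasing by the descent contract).
    """
    optics = OpticsConfig(fft_size=64)
    template = PupilModel(optics=optics, coeffs=np.zeros(12), blur_sigma=0.7)
    results = {}
    for span_um, key in ((1.0, "opt_1um"), (3.0, "opt_3um")):
        spec = OptimizationSpec(z_min=-500.0 * span_um, z_max=500.0 * span_um,
                                k=10, photons=3000.0, background=50.0)
        coeffs, report = optimize_psf(spec, template, n_starts=n_starts,
                                      n_iterations=n_iterations, seed=seed,
                                      window=window)
        results[key] = {"coeffs": coeffs, "history": report["history"],
                        "objective": report["objective"]}
    z_eval = np.linspace(-1500.0, 1500.0, 11)
    for key in ("opt_1um", "opt_3um"):
        pupil = template.with_coeffs(results[key]["coeffs"])
        curve = crlb_curve(pupil, 3000.0, 50.0, z_eval, window=window)
        results[key]["mean_crlb_z_pm1p5um"] = \
            float(curve["crlb_z_nm"].mean())
    return results
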