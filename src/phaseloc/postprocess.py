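"""Localization post-processing: precision filtering, merging of consecutive
localizations, fiducial-free 3D drift correction, and rendering.

Filtering removes localizations whose per-axis CRLB or residual chi-square
exceeds thresholds; the standard presets (per engineered-PSF family) are
lateral/axial CRLB cutoffs of 20/40 nm for astigmatic PSFs, 30/60 nm for
saddle-point PSFs, no CRLB cutoff for tetrapods, and chi2 <= 3 for all.

Merging collapses runs of localizations of the same blinking molecule in
consecutive frames (within lateral/axial capture radii, default 100/200 nm,
with a maximum disappearance gap of 0 frames) into a single record: photons
are summed, backgrounds averaged, and the position is the inverse-variance
(1/CRLB^2) weighted mean per axis.

Drift correction follows the redundant cross-correlation scheme: bin the
movie into non-overlapping time windows, render each as a 3D histogram,
cross-correlate all window pairs via FFT, locate each pairwise displacement
with subvoxel precision (intensity-weighted mean of voxels above 95% of the
peak), solve for per-window displacements by least squares over all pairs,
interpolate per-frame drift with a cubic spline, and subtract it.  The
estimated trace is anchored at zero for the first window: absolute sample
position is not observable from localizations alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft
from scipy.interpolate import CubicSpline

__all__ = [
    "FilterSpec",
    "DriftConfig",
    "DriftTrace",
    "filter_records",
    "merge_consecutive",
    "estimate_drift",
    "apply_drift",
    "render",
]

log = logging.getLogger(__name__)

FILTER_PRESETS: dict[str, tuple[float | None, float | None]] = {
    "astigmatic": (20.0, 40.0),
    "saddle": (30.0, 60.0),
    "tetrapod": (None, None),
}


@dataclass
class FilterSpec:
    """CRLB / chi-square quality thresholds (None disables a threshold)."""

    max_crlb_xy: float | None = None
    max_crlb_z: float | None = None
    max_chi2: float | None = 3.0

    def __post_init__(self) -> None:
        for v in (self.max_crlb_xy, self.max_crlb_z, self.max_chi2):
            if v is not None and v <= 0:
                raise ValueError("thresholds must be positive or None")

    @classmethod
    def from_preset(cls, name: str, max_chi2: float | None = 3.0) -> "FilterSpec":
        try:
            xy, z = FILTER_PRESETS[name]
        except KeyError:
            raise ValueError(f"unknown preset {name!r}; choose from "
                             f"{sorted(FILTER_PRESETS)}") from None
        return cls(max_crlb_xy=xy, max_crlb_z=z, max_chi2=max_chi2)


def filter_records(records: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Keep records with CRLB strictly below and chi2 at or below threshold."""
    keep = pd.Series(True, index=records.index)
    if spec.max_crlb_xy is not None:
        keep &= (records["crlb_x_nm"] < spec.max_crlb_xy)
        keep &= (records["crlb_y_nm"] < spec.max_crlb_xy)
    if spec.max_crlb_z is not None:
        keep &= records["crlb_z_nm"] < spec.max_crlb_z
    if spec.max_chi2 is not None:
        keep &= records["chi2"] <= spec.max_chi2
    return records[keep].reset_index(drop=True)


def merge_consecutive(records: pd.DataFrame, lateral_radius: float = 100.0,
                      axial_radius: float = 200.0, max_gap: int = 0,
                      ) -> pd.DataFrame:
    """Merge chains of localizations of the same molecule across frames.

    Records in increasing-frame order are linked when separated by at most
    ``max_gap`` skipped frames and within both capture radii of the chain's
    running position.  Each chain yields one record: photons summed,
    background and chi2 averaged, position the 1/CRLB^2-weighted mean, CRLB
    combined as an inverse-variance combination, frame = first frame.
    """
    if records.empty:
        return records.copy()
    df = records.sort_values("frame", kind="stable").reset_index(drop=True)
    frames = df["frame"].to_numpy()
    pos = df[["x_nm", "y_nm", "z_nm"]].to_numpy()
    crlb = df[["crlb_x_nm", "crlb_y_nm", "crlb_z_nm"]].to_numpy()
    open_chains: list[dict] = []
    done: list[list[int]] = []
    for i in range(len(df)):
        f = frames[i]
        still_open = []
        for ch in open_chains:
            if f - ch["last_frame"] - 1 > max_gap:
                done.append(ch["members"])
            else:
                still_open.append(ch)
        open_chains = still_open
        target = None
        for ch in open_chains:
            if ch["last_frame"] == f:
                continue  # one localization per molecule per frame
            dx = pos[i, 0] - ch["pos"][0]
            dy = pos[i, 1] - ch["pos"][1]
            dz = pos[i, 2] - ch["pos"][2]
            if dx * dx + dy * dy <= lateral_radius ** 2 and abs(dz) <= axial_radius:
                target = ch
                break
        if target is None:
            open_chains.append({"members": [i], "last_frame": f, "pos": pos[i]})
        else:
            target["members"].append(i)
            target["last_frame"] = f
            target["pos"] = pos[i]
    done.extend(ch["members"] for ch in open_chains)

    rows = []
    for members in done:
        sub = df.iloc[members]
        w = 1.0 / np.maximum(crlb[members] ** 2, 1e-300)
        wsum = w.sum(axis=0)
        merged_pos = (pos[members] * w).sum(axis=0) / wsum
        merged_crlb = np.sqrt(1.0 / wsum)
        rows.append({
            "frame": int(sub["frame"].iloc[0]),
            "x_nm": merged_pos[0], "y_nm": merged_pos[1], "z_nm": merged_pos[2],
            "photons": float(sub["photons"].sum()),
            "background": float(sub["background"].mean()),
            "chi2": float(sub["chi2"].mean()),
            "crlb_x_nm": merged_crlb[0], "crlb_y_nm": merged_crlb[1],
            "crlb_z_nm": merged_crlb[2],
            "score": float(sub["score"].max()),
            "n_merged": int(sub["n_merged"].sum()),
        })
    out = pd.DataFrame(rows, columns=list(records.columns))
    return out.sort_values("frame", kind="stable").reset_index(drop=True)


@dataclass
class DriftConfig:
    """Parameters of the redundant cross-correlation drift estimator."""

    window_frames: int = 10000
    voxel: float = 30.0
    max_drift: float = 6000.0
    min_locs_per_window: int = 50

    def __post_init__(self) -> None:
        if self.window_frames < 100:
            raise ValueError("window_frames must be >= 100")
        if self.voxel <= 0:
            raise ValueError("voxel must be positive")


@dataclass
class DriftTrace:
    """Per-frame 3D drift plus the per-window raw estimates behind it."""

    per_frame: np.ndarray             # (n_frames, 3) nm
    window_centers: np.ndarray        # (n_windows,) frame index midpoints
    window_displacements: np.ndarray  # (n_windows, 3) nm
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.per_frame = np.asarray(self.per_frame, dtype=float)
        if not np.all(np.isfinite(self.per_frame)):
            raise ValueError("drift trace must be finite")

    @property
    def n_frames(self) -> int:
        return self.per_frame.shape[0]

    def negated(self) -> "DriftTrace":
        return DriftTrace(per_frame=-self.per_frame,
                          window_centers=self.window_centers,
                          window_displacements=-self.window_displacements,
                          pairs=self.pairs)


def _histogram3d(pos: np.ndarray, edges) -> np.ndarray:
    h, _ = np.histogramdd(pos, bins=edges)
    return h


def _subvoxel_peak(corr: np.ndarray, level: float = 0.95) -> np.ndarray:
    """Intensity-weighted mean voxel position of the >= level * max region."""
    peak = corr.max()
    mask = corr >= level * peak
    w = corr[mask]
    idx = np.argwhere(mask)
    return (idx * w[:, None]).sum(axis=0) / w.sum()


def _pairwise_displacement(fa: np.ndarray, fb: np.ndarray, shape,
                           max_shift_vox: int) -> tuple[np.ndarray, float]:
    """Displacement (voxels) of histogram b relative to a from FFT xcorr."""
    corr = scipy.fft.irfftn(fa * np.conj(fb), s=shape)
    corr = np.fft.fftshift(corr)
    center = np.array([s // 2 for s in shape])
    lo = np.maximum(center - max_shift_vox, 0)
    hi = np.minimum(center + max_shift_vox + 1, shape)
    sub = corr[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    # correlation peaks at minus the displacement of b relative to a
    peak = _subvoxel_peak(sub) + lo - center
    return -peak, float(sub.max())


def estimate_drift(records: pd.DataFrame, config: DriftConfig | None = None,
                   n_frames: int | None = None) -> DriftTrace:
    """Estimate per-frame 3D drift from the localizations themselves.

    Requires at least two full time windows.  Windows with fewer than
    ``min_locs_per_window`` localizations are dropped from the least-squares
    system and bridged by the spline.
    """
    config = config or DriftConfig()
    if records.empty:
        raise ValueError("no localizations to estimate drift from")
    frames = records["frame"].to_numpy()
    if n_frames is None:
        n_frames = int(frames.max()) + 1
    n_windows = n_frames // config.window_frames
    if n_windows < 2:
        raise ValueError("need at least 2 full time windows for drift "
                         f"estimation (movie has {n_frames} frames, window "
                         f"is {config.window_frames})")
    pos = records[["x_nm", "y_nm", "z_nm"]].to_numpy()
    win_of = np.minimum(frames // config.window_frames, n_windows - 1)

    # common voxel grid, padded by the maximum expected drift
    vox = config.voxel
    lo = pos.min(axis=0) - vox
    hi = pos.max(axis=0) + vox
    edges = [np.arange(lo[d], hi[d] + 2 * vox, vox) for d in range(3)]
    shape = tuple(len(e) - 1 for e in edges)
    max_shift_vox = max(1, int(np.ceil(config.max_drift / vox)))
    # zero-pad by the shift search radius: correlation lags up to
    # max_shift_vox are then free of circular wraparound
    fft_shape = tuple(scipy.fft.next_fast_len(s + 2 * max_shift_vox + 1)
                      for s in shape)

    hists_f = {}
    counts = np.zeros(n_windows, dtype=int)
    for wdx in range(n_windows):
        sel = win_of == wdx
        counts[wdx] = int(sel.sum())
        if counts[wdx] >= config.min_locs_per_window:
            h = _histogram3d(pos[sel], edges)
            hists_f[wdx] = scipy.fft.rfftn(h, s=fft_shape)
    usable = sorted(hists_f)
    if len(usable) < 2:
        raise ValueError("fewer than 2 windows have enough localizations")
    if len(usable) < n_windows:
        log.info("drift: %d of %d windows below %d localizations, excluded",
                 n_windows - len(usable), n_windows, config.min_locs_per_window)

    rows = []
    obs = []
    for ii, wa in enumerate(usable):
        for wb in usable[ii + 1:]:
            shift_vox, peak = _pairwise_displacement(
                hists_f[wa], hists_f[wb], fft_shape, max_shift_vox)
            disp = shift_vox * vox
            rows.append({"window_a": wa, "window_b": wb, "dx_nm": disp[0],
                         "dy_nm": disp[1], "dz_nm": disp[2], "peak": peak})
            obs.append((wa, wb, disp))

    # least squares for per-window displacement, window usable[0] anchored at 0
    index = {w: i for i, w in enumerate(usable)}
    a_mat = np.zeros((len(obs) + 1, len(usable)))
    b_vec = np.zeros((len(obs) + 1, 3))
    for r, (wa, wb, disp) in enumerate(obs):
        a_mat[r, index[wb]] = 1.0
        a_mat[r, index[wa]] = -1.0
        b_vec[r] = disp
    a_mat[-1, 0] = 1.0  # anchor
    sol, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)

    centers = (np.asarray(usable) + 0.5) * config.window_frames
    t = np.arange(n_frames, dtype=float)
    per_frame = np.empty((n_frames, 3))
    for d in range(3):
        if len(usable) >= 2:
            spl = CubicSpline(centers, sol[:, d], bc_type="natural")
            tt = np.clip(t, centers[0], centers[-1])  # constant extrapolation
            per_frame[:, d] = spl(tt)
        else:
            per_frame[:, d] = sol[0, d]
    pairs = pd.DataFrame(rows)
    return DriftTrace(per_frame=per_frame,
                      window_centers=centers,
                      window_displacements=sol, pairs=pairs)


def apply_drift(records: pd.DataFrame, trace: DriftTrace) -> pd.DataFrame:
    """Subtract the per-frame drift from the record coordinates."""
    frames = records["frame"].to_numpy().astype(int)
    if frames.size and (frames.min() < 0 or frames.max() >= trace.n_frames):
        raise ValueError("records contain frames outside the drift trace")
    out = records.copy()
    d = trace.per_frame[frames]
    out["x_nm"] = out["x_nm"].to_numpy() - d[:, 0]
    out["y_nm"] = out["y_nm"].to_numpy() - d[:, 1]
    out["z_nm"] = out["z_nm"].to_numpy() - d[:, 2]
    return out


def render(records: pd.DataFrame, voxel: float = 20.0, dims: int = 3,
           n_shifts: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Average shifted histogram of the localizations.

    Averages ``n_shifts ** dims`` histograms whose grids are offset by
    fractions of a voxel; total intensity equals the record count exactly.
    Returns ``(image, origin_nm)`` with axes ordered (z,)y,x for ``dims``
    of 3 or (y, x) for 2.
    """
    if voxel <= 0:
        raise ValueError("voxel must be positive")
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    cols = ["x_nm", "y_nm", "z_nm"][:dims]
    if records.empty:
        return np.zeros((0,) * dims), np.zeros(dims)
    pos = records[list(reversed(cols))].to_numpy()  # (z,)y,x ordering
    lo = pos.min(axis=0) - voxel
    hi = pos.max(axis=0) + voxel
    nbins = np.ceil((hi - lo) / voxel).astype(int) + 1
    acc = None
    offsets = np.arange(n_shifts) * (voxel / n_shifts)
    from itertools import product
    for off in product(offsets, repeat=dims):
        edges = [lo[d] - off[d] + voxel * np.arange(nbins[d] + 1)
                 for d in range(dims)]
        h, _ = np.histogramdd(pos, bins=edges)
        acc = h if acc is None else acc + h
    return acc / n_shifts ** dims, lo
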