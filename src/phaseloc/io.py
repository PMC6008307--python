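"""File formats and configuration: TIFF stacks, localization tables, configs.

Localization tables are CSV with one leading '#' comment line carrying the
units and software version; coordinates are nm with the origin at the
frame's top-left pixel center, x along columns, y along rows, z relative to
the coverslip.  Write -> read round-trips are lossless at full float
precision (values are serialized with repr-exact formatting).
"""

from __future__ import annotations

from importlib.metadata import PackageNotFoundError, version
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .camera import CameraModel
from .localize import RECORD_COLUMNS

__all__ = [
    "read_stack",
    "write_stack",
    "read_localizations",
    "write_localizations",
    "expected_pixel_size",
    "load_config",
]

try:
    _VERSION = version("phaseloc")
except PackageNotFoundError:  # pragma: no cover - editable corner case
    _VERSION = "unknown"

TABLE_HEADER = (f"# phaseloc {_VERSION}; coordinates nm, origin at top-left "
                "pixel center, x=columns, y=rows, z from coverslip; "
                "photons/background in photon units")


def read_stack(path, camera: CameraModel | None = None) -> np.ndarray:
    """Multi-page TIFF as a float stack (n_pages, h, w), photon-converted.

    Page order is preserved.  Raises a diagnostic naming the page index on
    truncated/mixed-size files.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            pages = []
            shape = None
            for i, page in enumerate(tif.pages):
                try:
                    arr = page.asarray()
                except Exception as exc:
                    raise IOError(f"{path}: failed to read page {i}: {exc}") \
                        from exc
                if shape is None:
                    shape = arr.shape
                elif arr.shape != shape:
                    raise IOError(f"{path}: page {i} has shape {arr.shape}, "
                                  f"expected {shape}")
                pages.append(arr)
    except tifffile.TiffFileError as exc:
        raise IOError(f"{path}: not a readable TIFF: {exc}") from exc
    if not pages:
        raise IOError(f"{path}: empty TIFF")
    stack = np.stack(pages).astype(float)
    if camera is not None:
        stack = camera.adu_to_photons(stack)
    return stack


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (n, h, w) array as a multi-page 32-bit TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def write_localizations(path, records: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(TABLE_HEADER + "\n")
        records.to_csv(fh, index=False, float_format="%.17g")


def read_localizations(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def expected_pixel_size(camera_pitch_um: float, objective_mag: float,
                        relay_zoom: float = 1.0) -> float:
    """Image-plane pixel size in nm from the physical camera pitch.

    ``camera_pitch_um / (objective_mag * relay_zoom)``, e.g. a 13 um camera
    pixel behind a 60x objective and 2x relay gives 108.3 nm.
    """
    if camera_pitch_um <= 0 or objective_mag <= 0 or relay_zoom <= 0:
        raise ValueError("all inputs must be positive")
    return camera_pitch_um * 1000.0 / (objective_mag * relay_zoom)


_CONFIG_SECTIONS = {
    "optics": {"na", "wavelength", "n_immersion", "n_sample", "pixel_size",
               "focal_offset", "fft_size"},
    "camera": {"gain", "offset", "read_noise_var", "mode"},
    "detection": {"threshold", "z_min", "z_max", "dz", "window"},
    "fit": {"pupil_path"},
    "postprocess": {"preset", "max_crlb_xy", "max_crlb_z", "max_chi2",
                    "merge_lateral", "merge_axial", "merge_gap",
                    "drift_window", "drift_voxel", "max_drift",
                    "render_voxel", "render_shifts"},
    "paths": {"movie", "output_table", "output_image"},
}


def load_config(path) -> dict:
    """Read a YAML/JSON pipeline configuration, rejecting unknown keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    for section, content in cfg.items():
        if section not in _CONFIG_SECTIONS:
            raise ValueError(f"{path}: unknown section {section!r}")
        if content is None:
            continue
        for key in content:
            if key not in _CONFIG_SECTIONS[section]:
                raise ValueError(
                    f"{path}: unknown key {key!r} in section {section!r}")
    return {k: dict(v) if v else {} for k, v in cfg.items()}
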