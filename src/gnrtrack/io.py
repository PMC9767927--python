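"""Track tables, image stacks, configuration and run manifests.

The canonical track format is a plain CSV with the exact header

    frame,t,x_um,y_um,z_um,i_bottom,i_upper,dop,angle_deg,angle_defined

(UTF-8, '.' decimal separator).  Frames must be strictly increasing; the
DOP column must be consistent with the intensity columns.  Image stacks
are single-file multi-page 16-bit grayscale TIFFs; calibrations, configs
and manifests are JSON.
"""

from __future__ import annotations

import json
import platform
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

TRACK_COLUMNS = [
    "frame", "t", "x_um", "y_um", "z_um",
    "i_bottom", "i_upper", "dop", "angle_deg", "angle_defined",
]

__all__ = ["TRACK_COLUMNS", "read_track", "write_track", "read_stack",
           "write_stack", "write_manifest"]


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    frames = table["frame"].to_numpy()
    bad = np.flatnonzero(np.diff(frames) <= 0)
    if len(bad):
        raise ValueError(
            f"frame numbers not strictly increasing at line {int(bad[0]) + 2}"
        )
    i_b = table["i_bottom"].to_numpy(dtype=float)
    i_u = table["i_upper"].to_numpy(dtype=float)
    d = table["dop"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        recomputed = (i_b - i_u) / (i_b + i_u)
    both = np.isfinite(recomputed) & np.isfinite(d)
    if both.any() and np.max(np.abs(recomputed[both] - d[both])) > 1e-6:
        warnings.warn("dop column inconsistent with intensities (>1e-6)")
    return table[TRACK_COLUMNS]


def read_track(path: str | Path) -> pd.DataFrame:
    """Read and validate a track CSV."""
    table = pd.read_csv(path)
    return _validate(table)


def write_track(table: pd.DataFrame, path: str | Path) -> None:
    """Validate and write a track CSV (round-trip lossless to 1e-9)."""
    _validate(table).to_csv(path, index=False, float_format="%.12g")


def read_stack(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a float-count stack as multi-page 16-bit grayscale TIFF."""
    import tifffile

    data = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


def write_manifest(out_path: str | Path, params: dict, seed: int | None) -> None:
    """Write the run manifest (params, seed, versions) next to an output."""
    import gnrtrack

    manifest = {
        "output": str(out_path),
        "params": params,
        "seed": seed,
        "versions": {
            "gnrtrack": gnrtrack.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    p = Path(out_path)
    p.with_name(p.name + ".manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
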