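"""File formats: calibrated TIFF height maps with JSON sidecars, CSV tables.

Images travel as 32-bit float single-channel TIFF (heights in nm) plus a
JSON sidecar carrying the calibration (nm per pixel, scan size) and
provenance (seed, generator spec).  Tables are CSV with a commented header
line recording the seed so every output is traceable to its configuration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import TopographyImage

__all__ = [
    "write_topography",
    "read_topography",
    "write_table",
    "read_table",
    "write_force_curves",
    "read_force_curves",
]


def write_topography(
    image: TopographyImage, path: str | Path, seed: int | None = None, spec=None
) -> Path:
    """Write a height image as float32 TIFF plus a JSON calibration sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image.heights.astype(np.float32))
    sidecar = {
        "nm_per_px": image.nm_per_px,
        "scan_size_nm": image.scan_size_nm,
        "id": image.id,
        "seed": seed,
        "spec": dataclasses.asdict(spec) if dataclasses.is_dataclass(spec) else spec,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_topography(path: str | Path) -> TopographyImage:
    """Read a TIFF height map with its JSON sidecar."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing calibration sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    heights = np.asarray(tifffile.imread(path), dtype=float)
    return TopographyImage(
        heights=heights,
        nm_per_px=float(sidecar["nm_per_px"]),
        scan_size_nm=float(sidecar["scan_size_nm"]),
        id=str(sidecar.get("id", path.stem)),
    )


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> Path:
    """Write a CSV with a commented provenance header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# advafm seed={seed}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_force_curves(curves, path: str | Path, seed: int | None = None) -> Path:
    """Write force curves as long-format CSV (curve_id, depth_nm, force_nN)."""
    frames = [
        pd.DataFrame(
            {"curve_id": c.curve_id, "depth_nm": c.depth_nm, "force_nN": c.force_nN}
        )
        for c in curves
    ]
    return write_table(pd.concat(frames, ignore_index=True), path, seed=seed)


def read_force_curves(path: str | Path):
    """Read long-format force-curve CSV back into ForceCurve objects."""
    from .nanomech import ForceCurve

    df = read_table(path)
    return [
        ForceCurve(
            depth_nm=g["depth_nm"].to_numpy(),
            force_nN=g["force_nN"].to_numpy(),
            curve_id=str(cid),
        )
        for cid, g in df.groupby("curve_id", sort=False)
    ]
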